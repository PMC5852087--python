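# Pathway-step definitions for anaerobic/aerobic benzene degradation and the
# nitrogen cycle. Each step accepts a comma-separated set of KO and/or EC
# identifiers. Real KEGG/ExplorEnz identifiers are used where the gene has a
# public one; the putative anaerobic benzene carboxylase subunits (abcA, abcD)
# and benzoate-CoA ligase bzlA carry synthetic placeholder identifiers
# (K90xxx) because no KEGG orthology exists for them.
pathway	order	step	identifiers
benzene_carboxylation	1	abcA	K90001
benzene_carboxylation	2	abcD	K90002
benzene_carboxylation	3	bzlA	K90003,6.2.1.25
benzene_hydroxylation	1	ppsABC	K01841
benzene_hydroxylation	2	ppcC	K04102
benzene_hydroxylation	3	hcrA	K05798,1.3.7.9
benzoyl_coa_dearomatization	1	bamB	K19515,1.3.7.8
benzoyl_coa_dearomatization	2	bamC	K19516
benzoyl_coa_dearomatization	3	bamD	K19517
benzoyl_coa_dearomatization	4	bamE	K19518
benzoyl_coa_dearomatization	5	bamI	K19519
benzoyl_coa_dearomatization	6	bcrA/badF/bzdQ	K04112,K04115,1.3.7.8
beta_oxidation	1	bzdW	K07534
beta_oxidation	2	bzdX	K07535
beta_oxidation	3	bzdY	K07536
lower_pathway	1	pimE	K01692
lower_pathway	2	pimB	K00626
lower_pathway	3	acd	K00252
lower_pathway	4	gcdB	K20700
lower_pathway	5	gcdC	K20701
lower_pathway	6	gcdH	K00382
lower_pathway	7	pcaF	K00632,2.3.1.174
aerobic_benzene	1	tmoABCDEF	K15760,K15761,K15762,K15763,K15764,K15765
aerobic_benzene	2	dmpKLMNOP	K16243,K16244,K16245,K16246,K16242,K16249
aerobic_benzene	3	dmpB	K07104,1.13.11.2
aerobic_benzene	4	dmpC-I	K10217,K01821,K02554,K18364,K01666,K04103
nitrogen_cycle	1	narGHI	K00370,K00371,K00374
nitrogen_cycle	2	nirK	K00368,1.7.2.1
nitrogen_cycle	3	norB	K04561
nitrogen_cycle	4	nosZ	K00376
nitrogen_cycle	5	nrfAH	K03385,K15876
nitrogen_cycle	6	nsaA	K90010
nitrogen_cycle	7	narB	K00367
nitrogen_cycle	8	nifDH	K02586,K02588
nitrogen_cycle	9	amoAB	K10944,K10945
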