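# metatrx

Assembly-based metatranscriptome profiling for mixed microbial communities,
built around the analysis style used for anaerobic hydrocarbon-degrading
enrichment cultures (e.g. a benzene-degrading, nitrate-reducing consortium
dominated by *Peptococcaceae*). The package answers two questions from
community mRNA sequencing: **who is transcriptionally active** (taxon-level
mRNA profiles from contig taxonomy) and **which organisms carry each step of
a degradation pathway** (per-locus contribution to function).

It implements, as a tested reusable library plus CLI:

- **Read QC** — stepwise Q30 end-trimming, then length ≥ 40 bp, mean quality
  ≥ 30, IUPAC-alphabet and ≤ 3 N filters.
- **Low-complexity contig filtering** — contigs with > 90% of a single base,
  > 90% G+C or A+T, or a homopolymer run of ≥ 50 bases are removed.
- **Two-pass filtered LCA** — contig taxonomy from BLAST-tabular hit tables:
  hits must have e ≤ 10⁻⁴, bitscore > 50, alignment length > 100 nt, and
  bitscore within 10% of the best hit (MEGAN "top percent" convention); the
  contig is assigned the lowest common ancestor of the survivors' taxa.
  Contigs left unassigned by the first (megablast-like) table are retried
  against a second (blastn-like) table with identical filters.
- **Gene-level quantification** — primary mapped alignments credited to the
  gene with the largest overlap (ties discarded), giving counts and
  length-normalised depth; taxon profiles at any rank with an
  `unclassified` bucket.
- **Annotation merging** — KO/EC tables unioned per locus with provenance,
  plus EC numbers text-mined by matching protein-domain names against an
  enzyme-name table; functions projected onto editable pathway-step
  definitions (benzene carboxylation, benzoyl-CoA dearomatization,
  β-oxidation, aerobic oxygenases, nitrogen cycle, ...).
- **Contribution to function** — for loci *i* assigned to function *f* with
  expression *eᵢ* (depth by default),

  &nbsp;&nbsp;&nbsp;&nbsp;C(i, f) = 100 · eᵢ / Σⱼ eⱼ ,

  so two equally expressed loci each contribute 50%; plus a pathway-step
  relative-abundance report (percent of counted mRNA reads, log₁₀ display,
  zero steps removed).
- **A synthetic consortium simulator** — ranked taxonomy, skewed abundances
  with one dominant family, log-normal per-gene expression, a co-localized
  highly transcribed degradation gene cluster, reads with substitution
  errors and quality strings, an rRNA-contaminant fraction, alignments, and
  noisy hit tables — all with ground-truth labels, so the entire pipeline
  is testable end to end.

## Worked example

Simulate a six-family consortium whose designated family holds a 30% share
of the mRNA pool, sequence 50,000 error-free reads, and run the whole
pipeline:

```python
import metatrx as m

tree = m.generate_taxonomy(n_families=6, genera_per_family=2, seed=0)
truth = m.generate_community(tree, n_taxa=6, dominance=0.30, seed=0)
reads = m.simulate_reads(truth, n_reads=50_000, error_rate=0.0, seed=0)
hits = m.simulate_hit_table(truth.contig_taxon, tree, decoy_rate=0.0, seed=0)

paths = m.write_community(truth, reads, hits, "sim")
results = m.run_all(paths, "out")
print(results["taxon_profile"])
```

```
Family_1    29.670
Family_4    18.658
Family_5    14.502
Family_2    14.472
Family_3    12.632
Family_6    10.066
Name: percent_count_family, dtype: float64
```

The dominant family is recovered at 29.7% against a true share of 30%, and
the other five families match their true shares (18.55, 14.19, 14.34,
12.61, 10.30%) to within half a percentage point. The dominant taxon's
carboxylase subunit genes `abcA` and `abcD` are simulated at a 3:1
expression ratio; applying the contribution statistic to their recovered
depths:

```python
cov = results["coverage"]
pair = {g.symbol: g.locus_tag for g in truth.genes if g.symbol in ("abcA", "abcD")}
print(m.contribution({"benzene_carboxylase":
                      {t: float(cov.loc[t, "depth"]) for t in pair.values()}}))
```

```
              function       locus_tag  expression  contribution_pct
0  benzene_carboxylase  contig-100_0_1       963.5         75.645756
1  benzene_carboxylase  contig-100_0_2       310.2         24.354244
```

i.e. the 75%/25% split expected from the 3:1 ratio, recovered to within
read-sampling error.

The same run is available from the shell: `metatrx simulate --outdir sim`
followed by `metatrx run-all config.yaml`, or step by step through the
`qc`, `filter-contigs`, `assign-taxonomy`, `count`, `profile`, `annotate`
and `contribute` subcommands.

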