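# Methods

## Scope and data model

`metatrx` profiles an assembled metatranscriptome. It does not run external
tools (rRNA depletion, adapter trimming, assembly, gene prediction, read
mapping, BLAST searches, KO/domain annotation are consumed as their
standard file formats: FASTQ, FASTA, GFF3, SAM, 13-column BLAST tabular
with a subject-taxid column, NCBI `nodes.dmp`/`names.dmp`, annotation
TSVs). The package's own computations are the read filters, the contig
complexity filter, the two-pass filtered-LCA classifier, max-overlap read
counting, annotation merging with name→EC text matching, the
contribution-to-function statistic, and the simulator that exercises them.

## Read QC

Bases are trimmed stepwise from each read end while their quality is below
`min_q` (default Q30, single-base window semantics — the simplest reading
of "minimum quality at both ends"); interior bases are never removed, so
trimming is idempotent. The trimmed read is then rejected if shorter than
40 bp, if its mean quality is below 30, if it contains a non-IUPAC
character, or if it carries more than three Ns. The mean is computed on
the **trimmed** read: trimming precedes filtering, mirroring the
trim-then-filter order of the standard tools; this is a convention choice,
as the alternative (mean over the raw read) is equally defensible. The
reported rejection reason follows the fixed order length → mean quality →
alphabet → N count; the keep/reject verdict is order-independent. An empty
post-trim read is rejected as `min_length`. IUPAC codes other than
A/C/G/T/N are legal and pass the alphabet test.

## Contig complexity filter

Per contig: maximum single-base fraction, G+C fraction, A+T fraction and
longest homopolymer run. Removal thresholds follow the quoted rules
literally — fractions strictly greater than 0.9, run length inclusive at
50. Ambiguity codes (N etc.) count in the length denominator but never
toward a base tally or a run, so ambiguity alone can never trigger
removal. All four statistics are invariant under reverse complement
(tested by property). "More than 90% GC or AT" is read as two tests:
G+C > 0.9 or A+T > 0.9. Locus tags are rendered lowercase
(`contig-100_5019_1`); comparisons are case-insensitive because upstream
tools mix the casing.

## Two-pass filtered LCA

For one contig's hits, in order: e-value ceiling 10⁻⁴ (the search-time
cutoff, applied first so stale hits can never influence the top-percent
bound), bitscore strictly > 50, alignment length strictly > 100 nt, then
the top-deviation rule: keep hits with bitscore ≥ (1 − 0.10) × best
surviving bitscore. "Exceeding" and "more than" are strict; the derived
top bound is inclusive so the best hit always survives. The deviation is
measured on bitscore (the MEGAN top-percent convention); a `top_metric`
switch measures it on alignment length against the longest alignment
instead, for the alternative reading of "longest hit". The contig is
assigned the LCA — deepest node ancestral-or-self to every surviving hit's
taxon, computed as the longest common prefix of root-to-node paths. Hits
with taxon ids absent from the tree are dropped with a warning rather than
failing the contig; no MEGAN min-support threshold is applied. Contigs
unassigned after pass 1 are re-evaluated against the pass-2 (blastn-style)
table with identical filters; the pass label records the provenance.
Multiple reference databases are modelled as a single per-pass table, with
database provenance an optional hit attribute, never a filter.

Correctness is checked against an independently written brute-force oracle
(exhaustive filtering plus full path intersection) on 1000 random trees
(≤ 50 nodes) × random hit tables (≤ 20 hits), and by property tests:
permutation invariance, irrelevance of sub-threshold hits, LCA idempotence
and associativity over set union.

## Quantification and taxon profiles

Only primary, mapped alignments are counted; a read is credited to the
gene with the largest overlap on its contig, ties and zero-overlap reads
are discarded (an unambiguous-assignment approximation that avoids
fractional counts). Counting is unstranded, as no strandedness convention
is given for the underlying protocol. Depth is aligned read bases per gene
base. Taxon profiles attribute each gene's reads to its contig's
assignment lifted to the requested rank; assignments above the rank, and
unassigned contigs, go to `unclassified`, and percentages (counts by
default, depth by switch) sum to 100 including that bucket.

## Annotation and contribution

KO and EC tables are unioned per locus with per-assignment provenance;
malformed EC strings are skipped with a warning. Text-mined ECs come from
matching domain names against an enzyme-name table after normalisation
(lowercase, punctuation stripped, whitespace collapsed); an optional
token-set mode ignores word order. Exact-match-after-normalisation is the
default because it cannot hallucinate an EC; the fuzzier mode is an
interpretation, since the original mining rules are not fully specified.
Pathway definitions ship as an editable packaged TSV
(`src/metatrx/data/pathways.tsv`); a locus feeds a step when its function
set intersects the step's identifier set, may feed several steps, and is
then flagged ambiguous.

Contribution of a locus to a function is its fraction of the function's
total expression, in percent. Expression defaults to depth — it derives
from gene coverage and removes gene-length bias between loci of one
function — with a raw-count switch; both modes are tested. A locus mapped
to several functions contributes its full expression to each (ambiguity is
flagged separately, not split). Report output rounds to whole percent;
internal values keep full precision. Step abundances are percent of all
counted reads, displayed as log₁₀ with zero steps removed.

## The simulator

The generator emulates the structure of a long-running benzene-fed
denitrifying biofilm community: one dominant family (default 30% of the
mRNA pool) among several minor families, log-normal per-gene expression
(median 1, shape `expression_sigma`, default 1 — heavy-tailed, matching
the order-of-magnitude spread seen between degradation loci), and a
co-localized gene cluster in the dominant taxon (`abcA`, `abcD`, `bzlA` on
one contig) at fixed high expression 30/10/4 with the carboxylase subunits
at an exact 3:1 ratio. Read sampling weights are expression × gene length
**normalised within each taxon** and scaled by taxon abundance, so a
taxon's expected read share equals its abundance exactly — the property
the recovery tests measure; within a taxon this equals plain
expression × length weighting. Qualities are Q38 for correct calls and Q8
at substitution-error positions, placing bases on both sides of the Q30
trim rule. An rRNA fraction (binomially drawn) comes from a decoy sequence,
is flagged in the truth table, and is written unmapped in the SAM. Hit
tables give every contig a top hit to its true taxon (bitscore uniform in
[150, 300], length > 100), sister-taxon hits at 91–100% of the top score,
and optional wrong-clade decoys at ≤ 50 bitscore or ≤ 85% of the top —
deliberately straddling every classifier threshold so that correct
filtering is observable.

What it does **not** emulate: indel errors, paired-end reads, assembly
(contigs are emitted directly, so chimeras and fragmentation never occur),
strand-specific library artefacts, conserved-gene cross-mapping, or
database incompleteness. Passing recovery tests therefore demonstrate the
pipeline's correctness under clean mapping and honest hit tables, not
robustness to assembly or reference-database pathologies.

## Problem sizes and numerics

The recovery suite uses 6 families × 50,000 reads (runs in a few seconds);
the oracle-equivalence suite uses 1000 random instances. At 50,000 reads
the carboxylase pair collects ≈ 13,000 reads, so the binomial standard
error of its 75/25 split is ≈ 0.4 percentage points; the recovery test
asserts agreement at the whole-percent reporting precision (± 1 point,
≈ 2.6 σ), while the family-profile test asserts ± 2 points (≈ 10 σ).
Contribution sums are checked to 0.5 (the rounding tolerance of a
whole-percent report). Ties in max-overlap counting discard the read by
design; equal-bitscore hits are ordered by subject id for deterministic
output. All simulator randomness flows from one `numpy` PCG64 generator
per call; fixed seeds give byte-identical FASTQ/TSV/SAM outputs.

## Known limitations

- The LCA treats every surviving hit equally; no bitscore weighting or
  min-support cutoff.
- Depth uses query length for speed, ignoring clipping and indels (exact
  for the simulator's gapless reads).
- The text-mining default requires exact normalised name equality and will
  miss paraphrased enzyme names; the token-set mode helps but can
  over-match short names.
- Pathway-step identifier sets are curated, editable data, not derived
  from a live KEGG/BRENDA query.
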