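"""Synthetic benzene-degrading consortium with full ground truth.

Generates everything the pipeline consumes — a ranked taxonomy, a skewed
multi-taxon community (one dominant family) with per-gene log-normal
expression and a co-localized, highly transcribed degradation gene cluster,
error-bearing reads with quality strings and an rRNA-contaminant fraction,
read alignments, and noisy homology hit tables whose true source taxa are
known — so every downstream stage can be tested against truth labels
without external data.

All randomness flows from a single ``numpy`` generator per call; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .contigs import Contig, format_locus_tag, write_fasta
from .lca import Hit, write_hit_table
from .quant import GeneCall, write_gene_calls
from .readqc import Read, write_fastq
from .taxonomy import RANKS, TaxonomyTree

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Fixed expression levels (arbitrary units) and lengths (bp) of the
#: co-localized degradation cluster carried by the dominant taxon.  abcA and
#: abcD (carboxylase subunits) sit at an exact 3:1 expression ratio; all
#: three are far above the log-normal median of 1 ("highly transcribed").
CLUSTER_GENES = (
    ("abcA", 30.0, 1500, "K90001", None),
    ("abcD", 10.0, 1500, "K90002", None),
    ("bzlA", 4.0, 1560, "K90003", "6.2.1.25"),
)

#: One marker KO per non-dominant taxon, cycled, so the pathway report has
#: nitrogen-cycle steps to show.
MARKER_KOS = ("K00370", "K00368", "K04561", "K00376", "K02586")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Gene:
    """A gene of the mock community, placed on a contig."""

    locus_tag: str
    symbol: str
    taxid: int
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    expression: float
    ko: str | None = None
    ec: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CommunityTruth:
    """Fully specified mock consortium: who is there, what they transcribe."""

    tree: TaxonomyTree
    abundance: dict[int, float]
    genes: list[Gene]
    contigs: dict[str, str]              # contig id -> sequence
    contig_taxon: dict[str, int]         # contig id -> true taxon
    operons: dict[int, list[str]]        # taxon -> ordered locus tags sharing a contig
    rrna_sequence: str
    dominant_taxon: int
    seed: int

    def __post_init__(self) -> None:
        if abs(sum(self.abundance.values()) - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        if any(g.expression <= 0 for g in self.genes):
            raise ValueError("expression levels must be strictly positive")

    def gene_by_tag(self) -> dict[str, Gene]:
        return {g.locus_tag: g for g in self.genes}

    def gene_calls(self) -> list[GeneCall]:
        return [
            GeneCall(g.locus_tag, g.contig, g.start, g.end, g.strand)
            for g in self.genes
        ]

    def read_sampling_weights(self) -> np.ndarray:
        """Per-gene read probabilities: taxon abundance times the gene's
        share of its taxon's expression x length budget, so a taxon's
        expected read share equals its abundance exactly."""
        taxon_total: dict[int, float] = {}
        for g in self.genes:
            taxon_total[g.taxid] = taxon_total.get(g.taxid, 0.0) + g.expression * g.length
        w = np.array(
            [
                self.abundance[g.taxid] * g.expression * g.length / taxon_total[g.taxid]
                for g in self.genes
            ]
        )
        return w / w.sum()


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    locus_tag: str | None
    taxid: int | None
    contig: str | None
    position: int | None  # 0-based leftmost on the contig
    strand: str | None
    is_rrna: bool


@dataclass
class SimulatedReadSet:
    reads: list[Read]
    truth: list[ReadTruth]
    error_rate: float
    rrna_fraction: float
    seed: int

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.truth])


# -- taxonomy -------------------------------------------------------------


def generate_taxonomy(
    n_families: int,
    genera_per_family: int,
    seed: int = 0,
    species_per_genus: int = 1,
) -> TaxonomyTree:
    """Build a fully ranked taxonomy: one domain, up to two phyla (families
    split round-robin), one class and order per phylum, then
    ``n_families`` families each holding ``genera_per_family`` genera with
    ``species_per_genus`` species.  Deterministic for a fixed seed."""
    if n_families < 1 or genera_per_family < 1 or species_per_genus < 1:
        raise ValueError("taxon counts must be positive")
    tree = TaxonomyTree()
    next_id = 1
    tree.add_node(1, 1, "no rank", "root")
    next_id = 2
    tree.add_node(2, 1, "domain", "Bacteria")
    next_id = 3
    n_phyla = 2 if n_families > 1 else 1
    phylum_order: dict[int, int] = {}  # phylum index -> order taxid
    for p in range(n_phyla):
        phy, cls, ordr = next_id, next_id + 1, next_id + 2
        next_id += 3
        tree.add_node(phy, 2, "phylum", f"Phylum_{p + 1}")
        tree.add_node(cls, phy, "class", f"Class_{p + 1}")
        tree.add_node(ordr, cls, "order", f"Order_{p + 1}")
        phylum_order[p] = ordr
    for f in range(n_families):
        fam = next_id
        next_id += 1
        tree.add_node(fam, phylum_order[f % n_phyla], "family", f"Family_{f + 1}")
        for g in range(genera_per_family):
            gen = next_id
            next_id += 1
            tree.add_node(gen, fam, "genus", f"Genus_{f + 1}_{g + 1}")
            for s in range(species_per_genus):
                sp = next_id
                next_id += 1
                tree.add_node(
                    sp, gen, "species", f"Species_{f + 1}_{g + 1}_{s + 1}"
                )
    tree.validate()
    return tree


# -- community ------------------------------------------------------------


def generate_community(
    tree: TaxonomyTree,
    n_taxa: int,
    dominance: float = 0.30,
    expression_sigma: float = 1.0,
    seed: int = 0,
    genes_per_taxon: int = 8,
) -> CommunityTruth:
    """Draw a skewed community over ``n_taxa`` species of *tree*.

    The first selected species (one per family, round-robin) is designated
    dominant and receives abundance exactly ``dominance``; the remainder is
    split among the others with log-normal jitter.  Every taxon carries
    ``genes_per_taxon`` genes with log-normal expression (median 1, shape
    ``expression_sigma``); the dominant taxon additionally carries the
    co-localized degradation cluster on a single shared contig at fixed
    high expression.  Non-dominant taxa get one nitrogen-cycle marker KO
    each so the pathway report is populated.
    """
    if not 0 < dominance < 1:
        raise ValueError("dominance must lie in (0, 1)")
    if expression_sigma < 0:
        raise ValueError("expression_sigma must be non-negative")
    species = tree.species()
    if n_taxa > len(species):
        raise ValueError("n_taxa exceeds number of species in tree")
    rng = np.random.default_rng(seed)

    # one species per family first, then fill
    by_family: dict[int, list[int]] = {}
    for sp in species:
        fam = tree.ancestor_at_rank(sp, "family")
        by_family.setdefault(fam, []).append(sp)
    picked: list[int] = []
    round_idx = 0
    while len(picked) < n_taxa:
        for fam in sorted(by_family):
            members = by_family[fam]
            if round_idx < len(members) and len(picked) < n_taxa:
                picked.append(members[round_idx])
        round_idx += 1

    dominant = picked[0]
    abundance = {dominant: dominance}
    if n_taxa > 1:
        jitter = rng.lognormal(0.0, 0.5, size=n_taxa - 1)
        jitter = jitter / jitter.sum() * (1.0 - dominance)
        for taxid, a in zip(picked[1:], jitter):
            abundance[taxid] = float(a)
    else:
        abundance[dominant] = 1.0

    genes: list[Gene] = []
    contigs: dict[str, str] = {}
    contig_taxon: dict[str, int] = {}
    operons: dict[int, list[str]] = {}
    contig_idx = 0
    ko_serial = 50001

    def random_seq(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    for t_i, taxid in enumerate(picked):
        if taxid == dominant:
            # co-localized cluster on one shared contig
            contig_id = f"contig-100_{contig_idx}"
            spacer = 100
            pos = spacer
            parts = [random_seq(spacer)]
            cluster_tags = []
            for g_i, (symbol, expr, length, ko, ec) in enumerate(CLUSTER_GENES, 1):
                tag = format_locus_tag(100, contig_idx, g_i)
                genes.append(
                    Gene(tag, symbol, taxid, contig_id, pos + 1,
                         pos + length, "+", expr, ko, ec)
                )
                cluster_tags.append(tag)
                parts.append(random_seq(length))
                parts.append(random_seq(spacer))
                pos += length + spacer
            contigs[contig_id] = "".join(parts)
            contig_taxon[contig_id] = taxid
            operons[taxid] = cluster_tags
            contig_idx += 1
            n_extra = max(genes_per_taxon - len(CLUSTER_GENES), 0)
        else:
            n_extra = genes_per_taxon
        for g_i in range(n_extra):
            length = int(rng.integers(600, 1500))
            expr = float(rng.lognormal(0.0, expression_sigma))
            strand = "-" if (t_i + g_i) % 5 == 4 else "+"
            ko = None
            if taxid != dominant and g_i == 0:
                ko = MARKER_KOS[(t_i - 1) % len(MARKER_KOS)]
            else:
                ko = f"K{ko_serial}"
                ko_serial += 1
            contig_id = f"contig-100_{contig_idx}"
            flank = 50
            tag = format_locus_tag(100, contig_idx, 1)
            genes.append(
                Gene(tag, f"orf{contig_idx}", taxid, contig_id,
                     flank + 1, flank + length, strand, expr, ko, None)
            )
            contigs[contig_id] = random_seq(flank) + random_seq(length) + random_seq(flank)
            contig_taxon[contig_id] = taxid
            contig_idx += 1

    return CommunityTruth(
        tree=tree,
        abundance=abundance,
        genes=genes,
        contigs=contigs,
        contig_taxon=contig_taxon,
        operons=operons,
        rrna_sequence=random_seq(1500),
        dominant_taxon=dominant,
        seed=seed,
    )


# -- reads ----------------------------------------------------------------

#: Phred scores used for correct and erroneous base calls.
Q_CORRECT = 38
Q_ERROR = 8


def simulate_reads(
    truth: CommunityTruth,
    n_reads: int,
    read_length: int = 150,
    error_rate: float = 0.0,
    rrna_fraction: float = 0.0,
    seed: int = 0,
) -> SimulatedReadSet:
    """Sample reads from the community with truth labels.

    Genes are sampled with probability proportional to taxon abundance
    times the gene's within-taxon expression x length share; read start
    positions are uniform along the transcript.  Substitution errors occur
    independently per base at ``error_rate`` with quality dropped to
    Q8 (Q38 otherwise).  A binomially drawn ``rrna_fraction`` of reads
    comes from a decoy rRNA sequence and is flagged.
    """
    if read_length < 1:
        raise ValueError("read_length must be positive")
    if not 0 <= error_rate < 1 or not 0 <= rrna_fraction < 1:
        raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    reads: list[Read] = []
    truths: list[ReadTruth] = []
    if n_reads == 0:
        return SimulatedReadSet(reads, truths, error_rate, rrna_fraction, seed)

    n_rrna = int(rng.binomial(n_reads, rrna_fraction)) if rrna_fraction > 0 else 0
    n_mrna = n_reads - n_rrna
    weights = truth.read_sampling_weights()
    gene_idx = rng.choice(len(truth.genes), size=n_mrna, p=weights)

    def apply_errors(seq: str) -> tuple[str, tuple[int, ...]]:
        if error_rate == 0:
            return seq, (Q_CORRECT,) * len(seq)
        bases = list(seq)
        quals = [Q_CORRECT] * len(seq)
        err = rng.random(len(seq)) < error_rate
        for i in np.flatnonzero(err):
            alternatives = [b for b in "ACGT" if b != bases[i]]
            bases[i] = alternatives[int(rng.integers(3))]
            quals[i] = Q_ERROR
        return "".join(bases), tuple(quals)

    serial = 0
    for gi in gene_idx:
        g = truth.genes[int(gi)]
        transcript = truth.contigs[g.contig][g.start - 1 : g.end]
        if g.strand == "-":
            transcript = _revcomp(transcript)
        rlen = min(read_length, len(transcript))
        offset = int(rng.integers(0, len(transcript) - rlen + 1))
        seq, quals = apply_errors(transcript[offset : offset + rlen])
        read_id = f"read_{serial}"
        serial += 1
        if g.strand == "+":
            pos = g.start - 1 + offset
        else:
            pos = g.end - offset - rlen  # 0-based leftmost on the contig
        reads.append(Read(read_id, seq, quals))
        truths.append(
            ReadTruth(read_id, g.locus_tag, g.taxid, g.contig, pos, g.strand, False)
        )
    for _ in range(n_rrna):
        rlen = min(read_length, len(truth.rrna_sequence))
        offset = int(rng.integers(0, len(truth.rrna_sequence) - rlen + 1))
        seq, quals = apply_errors(truth.rrna_sequence[offset : offset + rlen])
        read_id = f"read_{serial}"
        serial += 1
        reads.append(Read(read_id, seq, quals))
        truths.append(ReadTruth(read_id, None, None, None, None, None, True))
    return SimulatedReadSet(reads, truths, error_rate, rrna_fraction, seed)


# -- hit tables -----------------------------------------------------------


def simulate_hit_table(
    contig_taxon: Mapping[str, int],
    tree: TaxonomyTree,
    decoy_rate: float = 0.0,
    seed: int = 0,
    n_sisters: int = 2,
) -> list[Hit]:
    """Noisy homology hits per contig with known true source taxa.

    Each contig gets a top hit to its true taxon (bitscore U[150,300],
    length > 100), sister hits (same family, different species) at 91-100%
    of the top bitscore, and — at ``decoy_rate`` per contig — a wrong-clade
    decoy whose bitscore is either <= 50 or <= 85% of the top, i.e. on the
    rejected side of every filter the classifier applies.
    """
    if not 0 <= decoy_rate <= 1:
        raise ValueError("decoy_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    species = tree.species()
    fam_of = {sp: tree.ancestor_at_rank(sp, "family") for sp in species}
    hits: list[Hit] = []
    for contig in sorted(contig_taxon):
        taxid = contig_taxon[contig]
        if taxid not in tree:
            raise ValueError(f"contig {contig} has unknown taxon {taxid}")
        top_score = float(rng.uniform(150, 300))
        hits.append(
            Hit(contig, f"acc_{taxid}_top", round(top_score, 1),
                int(rng.integers(120, 400)), 1e-30, 99.0, taxid)
        )
        fam = fam_of.get(taxid)
        sisters = [sp for sp in species if sp != taxid and fam_of[sp] == fam]
        if sisters and n_sisters > 0:
            chosen = rng.choice(
                sisters, size=min(n_sisters, len(sisters)), replace=False
            )
            for sister in chosen:
                hits.append(
                    Hit(contig, f"acc_{int(sister)}_rel",
                        round(top_score * float(rng.uniform(0.91, 1.0)), 1),
                        int(rng.integers(120, 400)), 1e-20, 95.0, int(sister))
                )
        if decoy_rate > 0 and rng.random() < decoy_rate:
            outsiders = [sp for sp in species if fam_of[sp] != fam]
            if outsiders:
                decoy = int(outsiders[int(rng.integers(len(outsiders)))])
                if rng.random() < 0.5:
                    score = float(rng.uniform(20, 50))
                else:
                    score = top_score * float(rng.uniform(0.5, 0.85))
                hits.append(
                    Hit(contig, f"acc_{decoy}_decoy", round(score, 1),
                        int(rng.integers(50, 400)), 1e-5, 80.0, decoy)
                )
    return hits


# -- file emission --------------------------------------------------------


def write_sam(
    readset: SimulatedReadSet, truth: CommunityTruth, path: str | os.PathLike
) -> None:
    """Write alignments as a text SAM; rRNA reads are emitted unmapped.

    Minus-strand reads are stored reverse-complemented with flag 16, as an
    aligner would report them.
    """
    contig_ids = sorted(truth.contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(truth.contigs[c])} for c in contig_ids],
    }
    tid = {c: i for i, c in enumerate(contig_ids)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read, rt in zip(readset.reads, readset.truth):
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.id
            if rt.is_rrna:
                a.is_unmapped = True
                a.query_sequence = read.sequence
                a.query_qualities = list(read.qualities)
            else:
                a.reference_id = tid[rt.contig]
                a.reference_start = rt.position
                a.mapping_quality = 42
                a.cigarstring = f"{len(read.sequence)}M"
                if rt.strand == "-":
                    a.is_reverse = True
                    a.query_sequence = _revcomp(read.sequence)
                    a.query_qualities = list(read.qualities)[::-1]
                else:
                    a.query_sequence = read.sequence
                    a.query_qualities = list(read.qualities)
            out.write(a)


def write_community(
    truth: CommunityTruth,
    readset: SimulatedReadSet,
    hits: Sequence[Hit],
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Emit the full fixture set into *outdir*; returns the path map.

    reads.fastq (Phred+33), contigs.fasta, genes.gff3, alignments.sam,
    hits.tsv (13-column outfmt-6 dialect), taxonomy nodes/names.dmp,
    abundance.tsv / genes.tsv / read_truth.tsv truth tables.
    """
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {name: os.path.join(outdir, fname) for name, fname in {
        "fastq": "reads.fastq",
        "fasta": "contigs.fasta",
        "gff": "genes.gff3",
        "sam": "alignments.sam",
        "hits": "hits.tsv",
        "abundance": "abundance.tsv",
        "genes": "genes.tsv",
        "read_truth": "read_truth.tsv",
        "ko": "ko.tsv",
        "ec": "ec.tsv",
    }.items()}
    write_fastq(readset.reads, paths["fastq"])
    write_fasta(
        [Contig(c, seq) for c, seq in sorted(truth.contigs.items())],
        paths["fasta"],
    )
    write_gene_calls(truth.gene_calls(), paths["gff"])
    write_sam(readset, truth, paths["sam"])
    write_hit_table(hits, paths["hits"])
    truth.tree.to_ncbi_dumps(outdir)
    paths["nodes"] = os.path.join(outdir, "nodes.dmp")
    paths["names"] = os.path.join(outdir, "names.dmp")
    pd.DataFrame(
        sorted(truth.abundance.items()),
        columns=["taxid", "abundance"],
    ).to_csv(paths["abundance"], sep="\t", index=False)
    pd.DataFrame([g.__dict__ for g in truth.genes]).to_csv(
        paths["genes"], sep="\t", index=False
    )
    readset.truth_frame().to_csv(paths["read_truth"], sep="\t", index=False)
    # annotation tables as an external annotator would deliver them
    with open(paths["ko"], "w") as fh:
        for g in truth.genes:
            if g.ko:
                fh.write(f"{g.locus_tag}\t{g.ko}\t100\n")
    with open(paths["ec"], "w") as fh:
        for g in truth.genes:
            if g.ec:
                fh.write(f"{g.locus_tag}\t{g.ec}\t100\n")
    return paths
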