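"""Gene-level read counting from alignments and taxon mRNA profiles.

Reads mapped to the assembled metatranscriptome are credited to predicted
genes by a max-overlap rule (primary mapped alignments only; ties and
zero-overlap reads are discarded), yielding per-locus counts and
length-normalised depth.  Counts are then rolled up by the taxon assigned
to each gene's contig, lifted to a chosen rank, to give the relative mRNA
abundance profile of the active community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .lca import TaxonAssignment
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

#: Coverage tables are locus-indexed DataFrames with columns
#: ``count``, ``length`` and ``depth``.
CoverageTable = pd.DataFrame


@dataclass(frozen=True)
class GeneCall:
    """A predicted protein-coding gene on a contig (1-based inclusive)."""

    locus_tag: str
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval for {self.locus_tag}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def count_reads(
    alignments: str | pysam.AlignmentFile,
    genes: Sequence[GeneCall],
    keep_reads: set[str] | None = None,
) -> pd.DataFrame:
    """Count primary mapped alignments per gene under the max-overlap rule.

    Each read is credited to the gene with the largest overlap on its
    contig; reads tying between genes or overlapping no gene are left
    uncounted.  Counting is unstranded.  ``keep_reads`` optionally
    restricts counting to a whitelist of read names (e.g. the QC-kept
    set).  Returns a coverage table indexed
    by locus tag with columns ``count``, ``length`` and ``depth`` (aligned
    read bases per gene base).
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        sam = pysam.AlignmentFile(str(alignments), "r")
    else:
        sam = alignments

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # interval tree is 0-based half-open
        trees.setdefault(g.contig, IntervalTree())[g.start - 1 : g.end] = g

    counts = {g.locus_tag: 0 for g in genes}
    bases = {g.locus_tag: 0 for g in genes}
    known_contigs = set(trees)
    for aln in sam:
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
            continue
        if keep_reads is not None and aln.query_name not in keep_reads:
            continue
        contig = aln.reference_name
        if contig not in known_contigs:
            logger.warning("alignment %s maps to unknown contig %s; skipped",
                           aln.query_name, contig)
            continue
        start, end = aln.reference_start, aln.reference_end
        best: GeneCall | None = None
        best_ov, tied = 0, False
        for iv in trees[contig][start:end]:
            ov = min(end, iv.end) - max(start, iv.begin)
            if ov > best_ov:
                best, best_ov, tied = iv.data, ov, False
            elif ov == best_ov and best is not None:
                tied = True
        if best is not None and not tied:
            counts[best.locus_tag] += 1
            bases[best.locus_tag] += aln.query_length or (end - start)

    table = pd.DataFrame(
        {
            "count": pd.Series(counts),
            "length": pd.Series({g.locus_tag: g.length for g in genes}),
        }
    )
    table["depth"] = pd.Series(bases) / table["length"]
    table.index.name = "locus_tag"
    return table


def taxon_profile(
    coverage: pd.DataFrame,
    gene_contig: Mapping[str, str],
    assignments: Sequence[TaxonAssignment],
    tree: TaxonomyTree,
    rank: str = "family",
    use: str = "count",
) -> pd.Series:
    """Percent of counted mRNA reads per taxon at *rank*.

    Each locus's reads are attributed to its contig's assigned taxon lifted
    to the requested rank; contigs that are unassigned, or assigned above
    the rank, feed the ``unclassified`` bucket.  ``use`` selects read
    counts (default, mirroring transcript-abundance profiles) or
    length-normalised ``depth``.  Percentages sum to 100.
    """
    assigned = {a.contig: a.taxid for a in assignments if a.assigned}
    weights: dict[str, float] = {}
    for locus, value in coverage[use].items():
        if value == 0:
            continue
        contig = gene_contig.get(locus)
        taxid = assigned.get(contig)
        label = "unclassified"
        if taxid is not None:
            anc = tree.ancestor_at_rank(taxid, rank)
            if anc is not None:
                label = tree.name[anc]
        weights[label] = weights.get(label, 0.0) + float(value)
    total = sum(weights.values())
    if total == 0:
        return pd.Series({"unclassified": 100.0})
    profile = pd.Series(weights).sort_values(ascending=False) / total * 100.0
    profile.name = f"percent_{use}_{rank}"
    return profile


# -- GFF3 plumbing --------------------------------------------------------


def read_gene_calls(gff_path) -> list[GeneCall]:
    """Read CDS/gene features from GFF3 (1-based inclusive, strand kept).

    The locus tag is taken from the ``locus_tag`` attribute, falling back
    to ``ID``.
    """
    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene"):
            continue
        locus = (feat.attributes.get("locus_tag") or feat.attributes.get("ID"))[0]
        genes.append(GeneCall(locus, feat.seqid, feat.start, feat.end, feat.strand))
    return genes


def write_gene_calls(genes: Iterable[GeneCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tmetatrx\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.locus_tag};locus_tag={g.locus_tag}\n"
            )
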