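"""Two-pass filtered-LCA taxonomic assignment of contigs from homology hits.

Each contig carries a table of local-alignment hits (BLAST tabular dialect
with a subject taxon id column).  Hits are filtered — e-value ceiling,
bitscore strictly above 50, alignment length strictly above 100 nt, and a
MEGAN-style top-percent rule keeping only hits within 10% of the best — and
the contig is assigned the lowest common ancestor of the surviving hits'
taxa.  Contigs left unassigned by the first (megablast-like) hit table are
retried against a second (blastn-like) table with identical filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

#: Column layout of the extended BLAST tabular (outfmt 6 + subject taxid).
HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore staxid"
).split()


@dataclass(frozen=True)
class Hit:
    """One homology match of a contig against a reference database."""

    query: str
    subject: str
    bitscore: float
    length: int
    evalue: float
    pident: float = 100.0
    taxid: int = 0
    database: str | None = None  # provenance only, never a filter

    def __post_init__(self) -> None:
        if self.bitscore < 0 or self.length < 0 or self.evalue < 0:
            raise ValueError(f"negative hit statistic for {self.query}")


@dataclass(frozen=True)
class LCAParams:
    """Filter thresholds for the LCA assignment.

    min_bitscore
        Hits must *exceed* this bitscore (strict >).  Default 50.
    min_len
        Alignment length must exceed this many nucleotides (strict >).
        Default 100.
    top_fraction
        Only hits that do not deviate more than this fraction from the best
        hit are used; the comparison is inclusive (>= (1-f) x best) so the
        best hit itself always survives.  Default 0.10.
    max_evalue
        E-value ceiling applied before all other filters.  Default 1e-4.
    top_metric
        "bitscore" (MEGAN top-percent convention, default) or "length"
        (deviation measured against the longest alignment instead).
    """

    min_bitscore: float = 50.0
    min_len: int = 100
    top_fraction: float = 0.10
    max_evalue: float = 1e-4
    top_metric: str = "bitscore"


@dataclass(frozen=True)
class TaxonAssignment:
    contig: str
    taxid: int | None
    pass_label: str  # "first" / "second" / "none"
    n_hits: int

    @property
    def assigned(self) -> bool:
        return self.taxid is not None


def filter_hits(hits: Sequence[Hit], params: LCAParams = LCAParams()) -> list[Hit]:
    """Apply the e-value, bitscore, length and top-deviation filters.

    All hits must share one query id.  The result is canonically sorted by
    descending bitscore then subject id, so it is independent of input
    order.
    """
    if len({h.query for h in hits}) > 1:
        raise ValueError("filter_hits requires hits of a single query")
    surviving = [
        h
        for h in hits
        if h.evalue <= params.max_evalue
        and h.bitscore > params.min_bitscore
        and h.length > params.min_len
    ]
    if surviving:
        if params.top_metric == "bitscore":
            best = max(h.bitscore for h in surviving)
            cutoff = (1.0 - params.top_fraction) * best
            surviving = [h for h in surviving if h.bitscore >= cutoff]
        elif params.top_metric == "length":
            best = max(h.length for h in surviving)
            cutoff = (1.0 - params.top_fraction) * best
            surviving = [h for h in surviving if h.length >= cutoff]
        else:
            raise ValueError(f"unknown top_metric {params.top_metric!r}")
    return sorted(surviving, key=lambda h: (-h.bitscore, h.subject))


def lca(taxa: Iterable[int], tree: TaxonomyTree) -> int:
    """Deepest node ancestral-or-self to every taxon in the set."""
    return tree.lca(taxa)


def assign_contig(
    hits: Sequence[Hit],
    tree: TaxonomyTree,
    params: LCAParams = LCAParams(),
    pass_label: str = "first",
) -> TaxonAssignment:
    """Filter a contig's hits and assign the LCA of the survivors.

    Hits whose taxon id is unknown to the tree are dropped with a warning
    rather than failing the contig.  With no surviving hits the contig is
    left unassigned.
    """
    contig = hits[0].query if hits else ""
    surviving = filter_hits(hits, params)
    known = [h for h in surviving if h.taxid in tree]
    for h in surviving:
        if h.taxid not in tree:
            logger.warning(
                "contig %s: dropping hit %s with unknown taxid %s",
                contig, h.subject, h.taxid,
            )
    if not known:
        return TaxonAssignment(contig, None, "none", 0)
    return TaxonAssignment(
        contig, lca((h.taxid for h in known), tree), pass_label, len(known)
    )


def two_pass_assign(
    pass1_hits: Mapping[str, Sequence[Hit]],
    pass2_hits: Mapping[str, Sequence[Hit]],
    tree: TaxonomyTree,
    params: LCAParams = LCAParams(),
    contigs: Iterable[str] | None = None,
) -> list[TaxonAssignment]:
    """Assign from pass-1 hits; retry only unassigned contigs on pass 2.

    ``contigs`` optionally fixes the universe (and output order) of contigs
    to report; by default it is the union of both tables' queries.  The
    pass label records which table produced each assignment.
    """
    if contigs is None:
        contigs = sorted(set(pass1_hits) | set(pass2_hits))
    out = []
    for contig in contigs:
        res = assign_contig(list(pass1_hits.get(contig, [])), tree, params, "first")
        if not res.assigned:
            res = assign_contig(
                list(pass2_hits.get(contig, [])), tree, params, "second"
            )
        if not res.assigned:
            res = TaxonAssignment(contig, None, "none", 0)
        else:
            res = TaxonAssignment(contig, res.taxid, res.pass_label, res.n_hits)
        out.append(res)
    return out


# -- tabular plumbing -----------------------------------------------------


def read_hit_table(
    path, columns: Sequence[str] = HIT_COLUMNS
) -> dict[str, list[Hit]]:
    """Read an extended BLAST outfmt-6 table into per-query hit lists."""
    df = pd.read_csv(str(path), sep="\t", names=list(columns), comment="#")
    hits: dict[str, list[Hit]] = {}
    for row in df.itertuples(index=False):
        hit = Hit(
            query=str(row.qseqid),
            subject=str(row.sseqid),
            bitscore=float(row.bitscore),
            length=int(row.length),
            evalue=float(row.evalue),
            pident=float(row.pident),
            taxid=int(row.staxid),
        )
        hits.setdefault(hit.query, []).append(hit)
    return hits


def write_hit_table(hits: Iterable[Hit], path) -> None:
    """Write hits in the extended 13-column outfmt-6 dialect."""
    rows = []
    for h in hits:
        rows.append(
            (
                h.query, h.subject, h.pident, h.length, 0, 0, 1, h.length,
                1, h.length, h.evalue, h.bitscore, h.taxid,
            )
        )
    pd.DataFrame(rows, columns=list(HIT_COLUMNS)).to_csv(
        str(path), sep="\t", header=False, index=False
    )


def assignments_to_frame(
    assignments: Sequence[TaxonAssignment], tree: TaxonomyTree
) -> pd.DataFrame:
    """TSV-ready table: contig, taxid, rank, lineage, pass, hit count."""
    rows = []
    for a in assignments:
        if a.assigned:
            rows.append(
                (
                    a.contig, a.taxid, tree.rank[a.taxid],
                    tree.lineage_names(a.taxid), a.pass_label, a.n_hits,
                )
            )
        else:
            rows.append((a.contig, None, "unassigned", "", a.pass_label, 0))
    return pd.DataFrame(
        rows,
        columns=["contig", "taxid", "rank", "lineage", "pass", "n_hits"],
    )
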