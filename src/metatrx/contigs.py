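"""Low-complexity contig filtering and locus-tag formatting.

Cross-assembled transcript contigs often include artefactual low-complexity
sequences.  A contig is removed when more than 90% of its bases are a single
base, more than 90% are G+C or A+T, or it contains a homopolymer run of 50
or more bases.  Fraction thresholds are strict (>0.9); the run threshold is
inclusive (>=50).  Ambiguity codes count toward contig length but never
toward any specific base tally or run.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str


@dataclass(frozen=True)
class ComplexityReport:
    """Per-contig complexity statistics and the filter verdict."""

    contig_id: str
    max_base_fraction: float
    gc_fraction: float
    at_fraction: float
    max_run: int
    passed: bool
    failing_rules: tuple[str, ...]


def complexity_report(
    contig: Contig,
    max_single_base: float = 0.9,
    max_gc_at: float = 0.9,
    max_run: int = 50,
) -> ComplexityReport:
    """Compute complexity statistics and apply the removal rules.

    Fails when max single-base fraction > ``max_single_base``, G+C or A+T
    fraction > ``max_gc_at``, or the longest homopolymer run of one
    unambiguous base is >= ``max_run`` bases.
    """
    seq = contig.sequence.upper()
    if not seq:
        raise ValueError(f"contig {contig.id} has empty sequence")
    n = len(seq)
    tallies = {b: seq.count(b) for b in "ACGT"}
    max_frac = max(tallies.values()) / n
    gc = (tallies["G"] + tallies["C"]) / n
    at = (tallies["A"] + tallies["T"]) / n
    longest = max(
        (len(list(grp)) for base, grp in groupby(seq) if base in "ACGT"),
        default=0,
    )
    failing = []
    if max_frac > max_single_base:
        failing.append("single_base")
    if gc > max_gc_at:
        failing.append("gc")
    if at > max_gc_at:
        failing.append("at")
    if longest >= max_run:
        failing.append("homopolymer_run")
    return ComplexityReport(
        contig.id, max_frac, gc, at, longest, not failing, tuple(failing)
    )


def filter_contigs(
    contigs: Iterable[Contig],
) -> tuple[list[Contig], list[tuple[Contig, ComplexityReport]]]:
    """Partition contigs into (kept, removed-with-reports); order preserved."""
    kept: list[Contig] = []
    removed: list[tuple[Contig, ComplexityReport]] = []
    for contig in contigs:
        report = complexity_report(contig)
        if report.passed:
            kept.append(contig)
        else:
            removed.append((contig, report))
    return kept, removed


def format_locus_tag(kmer: int, contig_index: int, gene_index: int) -> str:
    """Systematic locus tag ``contig-{kmer}_{contig#}_{gene#}``.

    The kmer component reflects the assembler run the contig came from
    (e.g. 100 for the default k=100 output); the following numbers are the
    contig number and the gene number on that contig.  Rendered lowercase;
    compare case-insensitively.
    """
    if kmer < 0 or contig_index < 0 or gene_index < 0:
        raise ValueError("locus tag components must be non-negative")
    return f"contig-{kmer}_{contig_index}_{gene_index}"


# -- FASTA plumbing -------------------------------------------------------


def read_fasta(path) -> list[Contig]:
    return [Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(contigs: Iterable[Contig], path) -> int:
    records = (
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    )
    return SeqIO.write(records, str(path), "fasta")
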