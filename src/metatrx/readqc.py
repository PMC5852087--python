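"""Read quality control: end trimming and length / quality / alphabet filters.

The rules mirror PRINSEQ-style single-read filtering: bases below Q30 are
stepwise-trimmed from both ends, then the trimmed read must be at least
40 bp long, have mean quality >= 30, contain only IUPAC nucleotide codes,
and carry at most three Ns.  rRNA removal and adapter clipping are assumed
to have happened upstream; the input FASTQ is taken as already depleted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: IUPAC nucleotide codes (N is legal but counted against the N limit).
IUPAC_NUCLEOTIDES = frozenset("ACGTURYSWKMBDHVN")

#: Rejection reasons in the order the predicates are applied.
REASONS = ("min_length", "mean_quality", "non_iupac", "too_many_n", "none")


@dataclass(frozen=True)
class Read:
    """A sequencing read: identifier, sequence and per-base Phred scores."""

    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class QCResult:
    """Outcome of :func:`qc_read`: keep/reject, trimmed read, reason."""

    kept: bool
    read: Read
    reason: str

    def __post_init__(self) -> None:
        if self.kept != (self.reason == "none"):
            raise ValueError("kept flag inconsistent with rejection reason")


def trim_ends(read: Read, min_q: int = 30) -> Read:
    """Stepwise-trim low-quality bases from both read ends.

    Bases are removed from the 5' end while their quality is below
    ``min_q``, then likewise from the 3' end.  Interior bases are never
    touched, so the operation is idempotent.  May return an empty read.
    """
    lo, hi = 0, len(read)
    while lo < hi and read.qualities[lo] < min_q:
        lo += 1
    while hi > lo and read.qualities[hi - 1] < min_q:
        hi -= 1
    if lo == 0 and hi == len(read):
        return read
    return Read(read.id, read.sequence[lo:hi], read.qualities[lo:hi])


def qc_read(
    read: Read,
    min_len: int = 40,
    min_mean_q: float = 30,
    max_n: int = 3,
    min_q: int = 30,
) -> QCResult:
    """Trim a read and test it against the four keep predicates.

    After end trimming at ``min_q`` the read is rejected if shorter than
    ``min_len``, if its mean quality is below ``min_mean_q`` (mean over the
    trimmed read), if it contains any non-IUPAC character, or if it has more
    than ``max_n`` Ns.  The reported reason is the first failing predicate
    in that fixed order; the verdict itself is order-independent.
    """
    trimmed = trim_ends(read, min_q=min_q)
    if len(trimmed) < min_len:
        return QCResult(False, trimmed, "min_length")
    if sum(trimmed.qualities) / len(trimmed) < min_mean_q:
        return QCResult(False, trimmed, "mean_quality")
    seq = trimmed.sequence.upper()
    if not set(seq) <= IUPAC_NUCLEOTIDES:
        return QCResult(False, trimmed, "non_iupac")
    if seq.count("N") > max_n:
        return QCResult(False, trimmed, "too_many_n")
    return QCResult(True, trimmed, "none")


# -- FASTQ plumbing -------------------------------------------------------


def read_fastq(path) -> Iterator[Read]:
    """Iterate reads from a Phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(
            rec.id,
            str(rec.seq),
            tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[Read], path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def qc_fastq(
    in_path,
    out_path,
    min_len: int = 40,
    min_mean_q: float = 30,
    max_n: int = 3,
    min_q: int = 30,
) -> dict[str, int]:
    """Filter a FASTQ file; returns per-reason counts (and 'kept')."""
    counts = {reason: 0 for reason in REASONS if reason != "none"}
    counts["kept"] = 0

    def kept_reads():
        for read in read_fastq(in_path):
            result = qc_read(read, min_len, min_mean_q, max_n, min_q)
            if result.kept:
                counts["kept"] += 1
                yield result.read
            else:
                counts[result.reason] += 1

    write_fastq(kept_reads(), out_path)
    logger.info("qc %s -> %s: %s", in_path, out_path, counts)
    return counts
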