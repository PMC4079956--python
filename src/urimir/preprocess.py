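"""Adapter trimming and quality/length filtering of small-RNA reads.

A small-RNA library read is insert + 3' adapter (and sometimes a 5' adapter
prefix).  Trimming locates the leftmost position where a prefix of the 3'
adapter aligns with at most ``max_mismatch_rate`` mismatches over an
overlap of at least ``min_overlap`` bases, and removes everything from
there on; a 5' adapter, when given, is removed from the read start first
(rightmost matching end, i.e. maximal trim).  The retention window is the
protocol default: 16-35 nt with mean phred quality >= 30.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refio import canonicalize_sequence

#: Sanger/phred+33 only; the highest quality emitted by current instruments.
MAX_PHRED = 42


@dataclass
class SmallRNARead:
    read_id: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mean_quality(self) -> float:
        return sum(self.qual) / len(self.qual) if self.qual else 0.0


@dataclass
class LengthHistogram:
    """Read-length distribution of retained reads plus stage totals."""

    counts: Counter = field(default_factory=Counter)
    n_raw: int = 0
    n_trimmed: int = 0
    n_retained: int = 0

    def add(self, length: int) -> None:
        self.counts[length] += 1
        self.n_retained += 1

    def fractions(self) -> dict[int, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {}
        return {k: v / total for k, v in sorted(self.counts.items())}

    def to_rows(self) -> list[tuple[int, int, float]]:
        fr = self.fractions()
        return [(length, self.counts[length], 100.0 * fr[length]) for length in fr]


def read_fastq(path) -> list[SmallRNARead]:
    """Parse a phred+33 FASTQ file.

    Qualities above phred 42 indicate a legacy +64 encoding and are
    rejected loudly rather than silently misinterpreted.
    """
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        if quals and max(quals) > MAX_PHRED:
            raise ValueError(
                f"{rec.id}: phred score {max(quals)} > {MAX_PHRED}; "
                "input does not look phred+33 encoded"
            )
        reads.append(
            SmallRNARead(rec.id, canonicalize_sequence(str(rec.seq)), list(quals))
        )
    return reads


def write_fastq(reads, path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qual)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_adapter3(seq: str, adapter3: str, min_overlap: int, max_mismatch_rate: float) -> int:
    """Leftmost start of the 3' adapter match, or len(seq) if none.

    At each candidate position the overlap is the shorter of the remaining
    read and the adapter; terminal partial overlaps of >= min_overlap count.
    """
    n = len(seq)
    for p in range(0, n - min_overlap + 1):
        overlap = min(len(adapter3), n - p)
        if overlap < min_overlap:
            break
        if _mismatches(seq[p : p + overlap], adapter3[:overlap]) <= max_mismatch_rate * overlap:
            return p
    return n


def find_adapter5(seq: str, adapter5: str, min_overlap: int, max_mismatch_rate: float) -> int:
    """End (exclusive) of a 5' adapter occupying the read start, or 0.

    Mirror image of the 3' search: the read may begin with a (suffix of
    the) 5' adapter; the rightmost matching end gives the maximal trim.
    """
    n = len(seq)
    for q in range(n, min_overlap - 1, -1):
        overlap = min(len(adapter5), q)
        if overlap < min_overlap:
            break
        if _mismatches(seq[q - overlap : q], adapter5[-overlap:]) <= max_mismatch_rate * overlap:
            return q
    return 0


def trim_adapters(
    read: SmallRNARead,
    adapter3: str,
    adapter5: str | None = None,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> SmallRNARead:
    """Remove adapters; qualities are trimmed in lockstep.

    A read with no adapter match is returned unchanged; a fully-adapter
    read (primer-dimer) collapses to an empty read.
    """
    if not 0 <= max_mismatch_rate < 0.5:
        raise ValueError("max_mismatch_rate must be in [0, 0.5)")
    seq, qual = read.seq, read.qual
    if adapter5:
        q = find_adapter5(seq, canonicalize_sequence(adapter5), min_overlap, max_mismatch_rate)
        seq, qual = seq[q:], qual[q:]
    if seq and adapter3:
        p = find_adapter3(seq, canonicalize_sequence(adapter3), min_overlap, max_mismatch_rate)
        seq, qual = seq[:p], qual[:p]
    return SmallRNARead(read.read_id, seq, qual)


def quality_length_filter(
    reads,
    min_len: int = 16,
    max_len: int = 35,
    min_mean_q: float = 30.0,
    n_raw: int | None = None,
):
    """Retain reads with min_len <= length <= max_len and mean phred >= min_mean_q.

    Returns (retained reads, LengthHistogram).  Pure subset operation.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    reads = list(reads)
    hist = LengthHistogram(n_raw=n_raw if n_raw is not None else len(reads))
    hist.n_trimmed = len(reads)
    retained = []
    for r in reads:
        if min_len <= len(r) <= max_len and r.mean_quality >= min_mean_q:
            retained.append(r)
            hist.add(len(r))
    return retained, hist
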