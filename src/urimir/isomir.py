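"""Mutually exclusive miRNA/isomiR read classification through a species cascade.

Each clean read is tested against every mature miRNA of the first species
tier (rat by default).  The categories, in fixed precedence order, are:

* ``IDENTICAL`` — read equals the mature sequence;
* ``SHORTER_PERFECT`` — read is a prefix or suffix of the mature, 1-5 nt short;
* ``END_SUBSTITUTION`` — equal length, exactly one difference, at the first
  or last position;
* ``ONE_EXTRA_BASE`` — one untemplated extra base at either end;
* ``TWO_EXTRA_BASES`` — two extra bases distributed over the ends (2+0, 1+1
  or 0+2);
* ``INTERNAL_MISMATCH`` — equal length, exactly one difference strictly
  inside the sequence;
* ``PRECURSOR`` — no mature-level category, but the read is an exact
  substring of a hairpin precursor.

The winning category for a read is the highest-precedence category achieved
by any record in the tier; only reads achieving it for exactly one record
yield a (unique) call — multi-miRNA reads are discarded from counting.
Reads a tier cannot place at all fall through to the next tier (mouse,
then human), and finally to other-ncRNA, exon, primer-dimer and dietary
accounting.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .preprocess import SmallRNARead, trim_adapters
from .refio import ReferenceTier, SequenceDB

logger = logging.getLogger(__name__)

#: Inserts shorter than this are primer-dimer residue, not quantifiable RNA.
MIN_INSERT = 16


class IsomiRCategory(Enum):
    IDENTICAL = "identical"
    SHORTER_PERFECT = "shorter_perfect"
    END_SUBSTITUTION = "end_substitution"
    ONE_EXTRA_BASE = "one_extra_base"
    TWO_EXTRA_BASES = "two_extra_bases"
    INTERNAL_MISMATCH = "internal_mismatch"
    PRECURSOR = "precursor"


#: Mature-level categories in precedence order (most exact explanation first).
MATURE_PRECEDENCE = [
    IsomiRCategory.IDENTICAL,
    IsomiRCategory.SHORTER_PERFECT,
    IsomiRCategory.END_SUBSTITUTION,
    IsomiRCategory.ONE_EXTRA_BASE,
    IsomiRCategory.TWO_EXTRA_BASES,
    IsomiRCategory.INTERNAL_MISMATCH,
]


def classify_against_mature(read_seq: str, mature_seq: str) -> IsomiRCategory | None:
    """Classify one read against one mature sequence (pure total function).

    Returns the first matching category in precedence order, or None.
    """
    if not read_seq or not mature_seq:
        raise ValueError("empty sequence")
    lr, lm = len(read_seq), len(mature_seq)
    if read_seq == mature_seq:
        return IsomiRCategory.IDENTICAL
    if 1 <= lm - lr <= 5 and (
        mature_seq.startswith(read_seq) or mature_seq.endswith(read_seq)
    ):
        return IsomiRCategory.SHORTER_PERFECT
    if lr == lm:
        diffs = [i for i in range(lr) if read_seq[i] != mature_seq[i]]
        if len(diffs) == 1:
            if diffs[0] in (0, lr - 1):
                return IsomiRCategory.END_SUBSTITUTION
            return IsomiRCategory.INTERNAL_MISMATCH
        return None
    if lr == lm + 1 and (read_seq[1:] == mature_seq or read_seq[:-1] == mature_seq):
        return IsomiRCategory.ONE_EXTRA_BASE
    if lr == lm + 2 and (
        read_seq[2:] == mature_seq
        or read_seq[1:-1] == mature_seq
        or read_seq[:-2] == mature_seq
    ):
        return IsomiRCategory.TWO_EXTRA_BASES
    return None


@dataclass(frozen=True)
class IsomiRCall:
    """A read's category/species assignment; ambiguous calls carry no id."""

    read_id: str
    mirna_id: str | None
    species: str
    category: IsomiRCategory
    unique: bool = True


class _TierIndex:
    """Hash indexes over one tier for O(1)-ish category lookups.

    The index is an optimization only: tests compare its output against a
    record-by-record scan with :func:`classify_against_mature`.
    """

    def __init__(self, tier: ReferenceTier):
        self.tier = tier
        self.exact: dict[str, list[str]] = tier.by_seq
        self.trunc: dict[str, set[str]] = {}
        self.by_length: dict[int, list[tuple[str, str]]] = {}
        for rec in tier.records:
            m = rec.mature_seq
            self.by_length.setdefault(len(m), []).append((rec.mirna_id, m))
            for k in range(1, 6):
                if len(m) - k < 1:
                    break
                self.trunc.setdefault(m[:-k], set()).add(rec.mirna_id)
                self.trunc.setdefault(m[k:], set()).add(rec.mirna_id)
        self.precursors: list[tuple[str, str]] = sorted(
            (rec.mirna_id, rec.precursor_seq)
            for rec in tier.records
            if rec.precursor_seq is not None
        )

    def _exact_ids(self, seq: str) -> set[str]:
        return set(self.exact.get(seq, ()))

    def candidates(self, read_seq: str, category: IsomiRCategory) -> set[str]:
        """Ids of records achieving exactly `category` for this read."""
        ids: set[str] = set()
        if category is IsomiRCategory.IDENTICAL:
            ids = self._exact_ids(read_seq)
        elif category is IsomiRCategory.SHORTER_PERFECT:
            hits = self.trunc.get(read_seq, set())
            # exclude records for which the read is identical (higher precedence)
            ids = {i for i in hits if self.tier.by_id[i].mature_seq != read_seq}
        elif category is IsomiRCategory.END_SUBSTITUTION:
            for b in "ACGT":
                if b != read_seq[0]:
                    ids |= self._exact_ids(b + read_seq[1:])
                if len(read_seq) > 1 and b != read_seq[-1]:
                    ids |= self._exact_ids(read_seq[:-1] + b)
        elif category is IsomiRCategory.ONE_EXTRA_BASE:
            if len(read_seq) > 1:
                ids = self._exact_ids(read_seq[1:]) | self._exact_ids(read_seq[:-1])
        elif category is IsomiRCategory.TWO_EXTRA_BASES:
            if len(read_seq) > 2:
                ids = (
                    self._exact_ids(read_seq[2:])
                    | self._exact_ids(read_seq[1:-1])
                    | self._exact_ids(read_seq[:-2])
                )
        elif category is IsomiRCategory.INTERNAL_MISMATCH:
            for mid, m in self.by_length.get(len(read_seq), ()):
                if classify_against_mature(read_seq, m) is IsomiRCategory.INTERNAL_MISMATCH:
                    ids.add(mid)
        return ids

    def precursor_hits(self, read_seq: str) -> set[str]:
        return {mid for mid, pseq in self.precursors if read_seq in pseq}


_INDEX_CACHE: dict[int, _TierIndex] = {}


def _index_for(tier: ReferenceTier) -> _TierIndex:
    idx = _INDEX_CACHE.get(id(tier))
    if idx is None or idx.tier is not tier:
        idx = _TierIndex(tier)
        _INDEX_CACHE[id(tier)] = idx
    return idx


def assign_read(read: SmallRNARead | str, tiers: list[ReferenceTier]) -> IsomiRCall | None:
    """Assign a read through the ordered species cascade.

    Within a tier the winning category is the highest-precedence one
    achieved by any mature record; a unique winner yields a call, several
    winners mark the read ambiguous (no id, excluded from counting).  A
    tier with no mature-level category tests the read as an exact unique
    substring of its precursors.  Only a tier yielding nothing lets the
    read fall through to the next tier.
    """
    if not tiers:
        raise ValueError("empty tier list")
    if isinstance(read, SmallRNARead):
        read_id, seq = read.read_id, read.seq
    else:
        read_id, seq = "<anonymous>", read
    if not seq or "N" in seq:
        return None
    for tier in tiers:
        idx = _index_for(tier)
        for category in MATURE_PRECEDENCE:
            ids = idx.candidates(seq, category)
            if ids:
                if len(ids) == 1:
                    return IsomiRCall(read_id, next(iter(ids)), tier.species, category)
                return IsomiRCall(read_id, None, tier.species, category, unique=False)
        hits = idx.precursor_hits(seq)
        if hits:
            if len(hits) == 1:
                return IsomiRCall(
                    read_id, next(iter(hits)), tier.species, IsomiRCategory.PRECURSOR
                )
            return IsomiRCall(read_id, None, tier.species, IsomiRCategory.PRECURSOR, False)
    return None


def detect_primer_dimer(
    read: SmallRNARead,
    adapter5: str | None,
    adapter3: str,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> bool:
    """True iff the post-trimming insert is < 16 nt, or the raw read matches
    the adapter5+adapter3 concatenation with <= 10% mismatches."""
    trimmed = trim_adapters(read, adapter3, adapter5, min_overlap, max_mismatch_rate)
    if len(trimmed) < MIN_INSERT:
        return True
    if adapter5:
        concat = adapter5 + adapter3
        n = min(len(read.seq), len(concat))
        if n and sum(a != b for a, b in zip(read.seq[:n], concat[:n])) <= 0.1 * n and abs(
            len(read.seq) - len(concat)
        ) <= 2:
            return True
    return False


@dataclass
class ClassificationProfile:
    """Per-sample tally behind the read-composition and isomiR breakdowns.

    ``class_totals`` partitions the clean reads exactly:
    miRs + other_ncRNA + exon + primer_dimer + ambiguous + unaligned = total.
    """

    sample_id: str
    mirna_counts: Counter = field(default_factory=Counter)  # (mirna_id, category) -> n
    class_totals: Counter = field(default_factory=Counter)
    category_totals: Counter = field(default_factory=Counter)  # IsomiRCategory -> n
    tier_totals: Counter = field(default_factory=Counter)  # species -> n
    dietary: Counter = field(default_factory=Counter)  # genome -> n
    total_clean: int = 0
    total_mirna_mapped: int = 0

    def merged_counts(self) -> Counter:
        """Per-miRNA counts merged across all isomiR categories."""
        merged: Counter = Counter()
        for (mid, _cat), n in self.mirna_counts.items():
            merged[mid] += n
        return merged

    def proportions(self) -> dict[str, float]:
        """Class proportions over total clean reads."""
        if self.total_clean == 0:
            return {}
        return {k: v / self.total_clean for k, v in self.class_totals.items()}

    def category_proportions(self) -> dict[str, float]:
        """IsomiR-category proportions over miRNA-mapped reads."""
        if self.total_mirna_mapped == 0:
            return {}
        return {
            cat.value: self.category_totals[cat] / self.total_mirna_mapped
            for cat in IsomiRCategory
        }


def profile_sample(
    reads,
    tiers: list[ReferenceTier],
    dbs: list[SequenceDB] | None = None,
    sample_id: str = "sample",
) -> tuple[ClassificationProfile, list[SmallRNARead]]:
    """Give every trimmed read exactly one terminal label.

    Evaluation order: primer_dimer (insert < 16 nt) -> miRNA cascade ->
    other-ncRNA -> exon -> unaligned.  ``dbs`` is the ordered list of
    auxiliary databases (other_ncrna first, exon second).  Returns the
    profile plus the unaligned read set for downstream dietary analysis.
    """
    dbs = dbs or []
    profile = ClassificationProfile(sample_id=sample_id)
    unaligned: list[SmallRNARead] = []
    for read in reads:
        profile.total_clean += 1
        if len(read) < MIN_INSERT:
            profile.class_totals["primer_dimer"] += 1
            continue
        call = assign_read(read, tiers)
        if call is not None:
            if call.unique:
                profile.class_totals["miRs"] += 1
                profile.total_mirna_mapped += 1
                profile.mirna_counts[(call.mirna_id, call.category)] += 1
                profile.category_totals[call.category] += 1
                profile.tier_totals[call.species] += 1
            else:
                profile.class_totals["ambiguous"] += 1
            continue
        labelled = False
        for db in dbs:
            if db.contains(read.seq) is not None:
                profile.class_totals[db.name] += 1
                labelled = True
                break
        if not labelled:
            profile.class_totals["unaligned"] += 1
            unaligned.append(read)
    return profile, unaligned


@dataclass
class UnalignedReport:
    """Dietary cascade proportions and over-represented unaligned sequences."""

    n_unaligned: int
    per_genome: dict[str, int]
    top_sequences: list[tuple[str, int, float]]  # (sequence, count, fraction of pool)


def analyze_unaligned(
    reads, dietary_dbs: list[SequenceDB], top_k: int = 10
) -> UnalignedReport:
    """Cascade unaligned reads through dietary genomes (wheat -> corn ->
    soybean order as given), then tally identical leftover sequences."""
    reads = list(reads)
    n = len(reads)
    per_genome: dict[str, int] = {db.name: 0 for db in dietary_dbs}
    leftovers: list[str] = []
    for read in reads:
        seq = read.seq if isinstance(read, SmallRNARead) else read
        for db in dietary_dbs:
            if db.contains(seq) is not None:
                per_genome[db.name] += 1
                break
        else:
            leftovers.append(seq)
    tally = Counter(leftovers)
    top = [
        (seq, count, count / n)
        for seq, count in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
    ]
    return UnalignedReport(n_unaligned=n, per_genome=per_genome, top_sequences=top)


def coverage_filter(query_length: int, aligned_length: int, threshold: float = 0.85) -> bool:
    """True iff aligned/query strictly exceeds the coverage threshold."""
    if not 0 < aligned_length <= query_length:
        raise ValueError("require 0 < aligned_length <= query_length")
    return aligned_length / query_length > threshold
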