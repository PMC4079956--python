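"""Synthetic small-RNA libraries and qPCR Ct matrices with known ground truth.

The generator emulates the composition of a gel-selected (18-30 nt) urinary
small-RNA library: reads drawn from mature miRNAs and each isomiR class,
precursor-hairpin fragments, other-ncRNA and exon fragments, dietary
contaminants, primer-dimers and random sequence, each read wrapped with a
3' (and optionally 5') adapter and per-base phred qualities.  Every read
carries a truth row, so classifier output can be scored exactly.

Precursor fragments are rejection-sampled until they are unclassifiable at
the mature level, making truth classes and classifier categories a
bijection.  All randomness flows from a single seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isomir import IsomiRCategory, classify_against_mature
from .preprocess import SmallRNARead
from .refio import MiRNARecord, ReferenceTier, SequenceDB

#: Default ligation adapters (fixed arbitrary 20-mers shipped with the package).
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCG"

#: Read classes the generator can emit.
READ_CLASSES = [
    "identical",
    "shorter",
    "end_substitution",
    "one_extra_base",
    "two_extra_bases",
    "internal_mismatch",
    "precursor_fragment",
    "other_ncrna",
    "exon",
    "dietary",
    "primer_dimer",
    "random",
]

#: Truth class -> classifier category for miRNA-derived classes.
CLASS_TO_CATEGORY = {
    "identical": IsomiRCategory.IDENTICAL,
    "shorter": IsomiRCategory.SHORTER_PERFECT,
    "end_substitution": IsomiRCategory.END_SUBSTITUTION,
    "one_extra_base": IsomiRCategory.ONE_EXTRA_BASE,
    "two_extra_bases": IsomiRCategory.TWO_EXTRA_BASES,
    "internal_mismatch": IsomiRCategory.INTERNAL_MISMATCH,
    "precursor_fragment": IsomiRCategory.PRECURSOR,
}

_BASES = "ACGT"


@dataclass
class CompositionSpec:
    """Fractions over read classes plus adapter and quality models.

    Fractions must be non-negative and sum to 1 (within 1e-9).
    """

    fractions: dict[str, float]
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str | None = None
    mean_q: float = 38.0
    sd_q: float = 2.0

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(READ_CLASSES)
        if unknown:
            raise ValueError(f"unknown read classes: {sorted(unknown)}")
        vals = list(self.fractions.values())
        if any(v < 0 for v in vals):
            raise ValueError("fractions must be non-negative")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {sum(vals)}, expected 1")


@dataclass
class GroundTruth:
    """One row per emitted read plus realized per-class totals."""

    reads: pd.DataFrame  # read_id, read_class, source_id, species
    class_counts: dict[str, int]
    mirna_counts: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _distinct_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[rng.integers(0, 3)]


def make_demo_references(
    seed: int = 0,
    n_rat: int = 40,
    n_mouse: int = 25,
    n_human: int = 15,
    n_db_seqs: int = 8,
    db_seq_len: int = 400,
) -> tuple[list[ReferenceTier], dict[str, SequenceDB]]:
    """Random but reproducible reference tiers and auxiliary databases.

    Mature sequences are 19-25 nt; each is embedded in a ~70 nt hairpin
    precursor.  Auxiliary databases (other_ncrna, exon, wheat, corn,
    soybean) are longer random sequences matched by substring containment.
    """
    rng = np.random.default_rng(seed)
    tiers = []
    for species, prefix, n in (
        ("rat", "rno", n_rat),
        ("mouse", "mmu", n_mouse),
        ("human", "hsa", n_human),
    ):
        records = []
        for i in range(n):
            mature = _random_seq(rng, int(rng.integers(19, 26)))
            left = _random_seq(rng, int(rng.integers(15, 26)))
            right = _random_seq(rng, int(rng.integers(15, 26)))
            arm = "-5p" if i % 2 == 0 else "-3p"
            records.append(
                MiRNARecord(
                    mirna_id=f"{prefix}-miR-{i + 1}{arm}",
                    species=species,
                    mature_seq=mature,
                    precursor_id=f"{prefix}-miR-{i + 1}",
                    precursor_seq=left + mature + right,
                )
            )
        tiers.append(ReferenceTier(species=species, records=records))
    dbs = {}
    for name in ("other_ncrna", "exon", "wheat", "corn", "soybean"):
        dbs[name] = SequenceDB(
            name=name,
            sequences={
                f"{name}_{j + 1}": _random_seq(rng, db_seq_len) for j in range(n_db_seqs)
            },
        )
    return tiers, dbs


def _make_insert(
    rng: np.random.Generator,
    read_class: str,
    tiers: list[ReferenceTier],
    dbs: dict[str, SequenceDB],
    mirna_weights: dict[str, float] | None,
) -> tuple[str, str, str]:
    """Return (insert, source_id, species) for one read of `read_class`."""
    if read_class in CLASS_TO_CATEGORY and read_class != "precursor_fragment":
        tier = tiers[0]
        if mirna_weights:
            ids = sorted(mirna_weights)
            w = np.array([mirna_weights[i] for i in ids], dtype=float)
            rec = tier.by_id[ids[rng.choice(len(ids), p=w / w.sum())]]
        else:
            rec = tier.records[rng.integers(0, len(tier.records))]
        m = rec.mature_seq
        if read_class == "identical":
            insert = m
        elif read_class == "shorter":
            k = int(rng.integers(1, min(5, len(m) - 16) + 1))
            insert = m[:-k] if rng.integers(0, 2) else m[k:]
        elif read_class == "end_substitution":
            pos = 0 if rng.integers(0, 2) else len(m) - 1
            insert = m[:pos] + _distinct_base(rng, m[pos]) + m[pos + 1 :]
        elif read_class == "one_extra_base":
            b = _BASES[rng.integers(0, 4)]
            insert = b + m if rng.integers(0, 2) else m + b
        elif read_class == "two_extra_bases":
            b1, b2 = (_BASES[i] for i in rng.integers(0, 4, size=2))
            split = rng.integers(0, 3)  # 2+0, 1+1, 0+2
            insert = [b1 + b2 + m, b1 + m + b2, m + b1 + b2][split]
        else:  # internal_mismatch
            pos = int(rng.integers(1, len(m) - 1))
            insert = m[:pos] + _distinct_base(rng, m[pos]) + m[pos + 1 :]
        return insert, rec.mirna_id, tier.species
    if read_class == "precursor_fragment":
        tier = tiers[0]
        with_prec = [r for r in tier.records if r.precursor_seq is not None]
        if not with_prec:
            raise ValueError("precursor_fragment requested but tier has no precursors")
        all_matures = [r.mature_seq for t in tiers for r in t.records]
        for _ in range(200):
            rec = with_prec[rng.integers(0, len(with_prec))]
            p = rec.precursor_seq
            length = int(rng.integers(16, 31))
            start = int(rng.integers(0, len(p) - length + 1))
            frag = p[start : start + length]
            if all(classify_against_mature(frag, m) is None for m in all_matures):
                return frag, rec.mirna_id, tier.species
        raise RuntimeError("could not sample an unclassifiable precursor fragment")
    if read_class in ("other_ncrna", "exon", "dietary"):
        db = dbs["wheat" if read_class == "dietary" else read_class]
        names = sorted(db.sequences)
        name = names[rng.integers(0, len(names))]
        src = db.sequences[name]
        length = int(rng.integers(16, 31))
        start = int(rng.integers(0, len(src) - length + 1))
        return src[start : start + length], name, db.name
    if read_class == "random":
        return _random_seq(rng, int(rng.integers(16, 31))), "random", "none"
    raise ValueError(f"unhandled read class {read_class}")


def generate_reads(
    tiers: list[ReferenceTier],
    dbs: dict[str, SequenceDB],
    spec: CompositionSpec,
    n_reads: int,
    seed: int,
    sample_id: str = "s1",
    mirna_weights: dict[str, float] | None = None,
) -> tuple[list[SmallRNARead], GroundTruth]:
    """Emit `n_reads` reads (insert + adapters + qualities) with truth rows.

    Primer-dimer reads are adapter5+adapter3 concatenations with insert
    length < 16 (here: empty insert).  Deterministic given `seed`.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    classes = [c for c in READ_CLASSES if spec.fractions.get(c, 0.0) > 0]
    for c in classes:
        if c in CLASS_TO_CATEGORY and not tiers:
            raise ValueError(f"class {c} requested but no reference tiers given")
        if c in ("other_ncrna", "exon") and c not in dbs:
            raise ValueError(f"class {c} requested but no {c} database given")
        if c == "dietary" and "wheat" not in dbs:
            raise ValueError("dietary class requested but no wheat database given")
    probs = np.array([spec.fractions[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(classes), size=n_reads, p=probs)
    a5 = spec.adapter5 or ""
    reads: list[SmallRNARead] = []
    rows = []
    class_counts: dict[str, int] = {c: 0 for c in classes}
    mirna_counts: dict[str, int] = {}
    for i, ci in enumerate(draws):
        read_class = classes[ci]
        class_counts[read_class] += 1
        if read_class == "primer_dimer":
            insert, source_id, species = "", "primer_dimer", "none"
            full = a5 + spec.adapter3
        else:
            insert, source_id, species = _make_insert(
                rng, read_class, tiers, dbs, mirna_weights
            )
            full = a5 + insert + spec.adapter3
        if read_class in CLASS_TO_CATEGORY:
            mirna_counts[source_id] = mirna_counts.get(source_id, 0) + 1
        qual = np.clip(
            np.rint(rng.normal(spec.mean_q, spec.sd_q, size=len(full))), 2, 40
        ).astype(int)
        read_id = f"{sample_id}:{i:07d}"
        reads.append(SmallRNARead(read_id, full, qual.tolist()))
        rows.append((read_id, read_class, source_id, species))
    truth = GroundTruth(
        reads=pd.DataFrame(rows, columns=["read_id", "read_class", "source_id", "species"]),
        class_counts=class_counts,
        mirna_counts=mirna_counts,
    )
    return reads, truth


def spike_differential(
    base_profile: dict[str, float],
    fc_map: dict[str, float],
    groups: dict[str, str],
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Per-sample expected-count weights with group-wise spiked fold changes.

    Samples in the second (treated) group get expectation
    ``base_profile[m] * fc_map[m]``; fold changes must be positive ratios.
    """
    unknown = set(fc_map) - set(base_profile)
    if unknown:
        raise ValueError(f"fc_map names unknown miRNAs: {sorted(unknown)}")
    if any(fc <= 0 for fc in fc_map.values()):
        raise ValueError("fold changes must be positive ratios")
    group_names = sorted(set(groups.values()))
    if len(group_names) != 2:
        raise ValueError("exactly two groups required")
    treated = group_names[1]
    weights: dict[str, dict[str, float]] = {}
    for sample, grp in groups.items():
        w = dict(base_profile)
        if grp == treated:
            for m, fc in fc_map.items():
                w[m] = w[m] * fc
        weights[sample] = w
    return weights


def sample_count_matrix(
    weights: dict[str, dict[str, float]], depth: int, seed: int
) -> pd.DataFrame:
    """Multinomial counts per sample from expected-count weights."""
    rng = np.random.default_rng(seed)
    samples = sorted(weights)
    mirnas = sorted(weights[samples[0]])
    mat = {}
    for s in samples:
        w = np.array([weights[s][m] for m in mirnas], dtype=float)
        mat[s] = rng.multinomial(depth, w / w.sum())
    return pd.DataFrame(mat, index=mirnas)


def generate_ct_matrix(
    n_mirna: int,
    n_per_group: int,
    fc_map: dict[str, float],
    base_ct_mean: float = 26.0,
    base_ct_sd: float = 3.0,
    ct_sd: float = 0.5,
    dropout_ct_threshold: float = 35.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], pd.Series]:
    """Group-structured Ct matrix with additive normal noise and dropouts.

    `fc_map` uses the signed fold-change convention (+r = up r-fold in the
    treated group, -r = down r-fold); a true ratio r lowers the treated
    mean Ct by log2(r).  Values above `dropout_ct_threshold` become NaN
    ("Undetermined" on disk).  Returns (matrix, groups, true mean Ct).
    """
    if ct_sd < 0:
        raise ValueError("ct_sd must be >= 0")
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group for a Welch test")
    rng = np.random.default_rng(seed)
    assays = [f"m{i + 1}" for i in range(n_mirna)]
    unknown = set(fc_map) - set(assays)
    if unknown:
        raise ValueError(f"fc_map names unknown assays: {sorted(unknown)}")
    samples = [f"C{i + 1}" for i in range(n_per_group)] + [
        f"T{i + 1}" for i in range(n_per_group)
    ]
    groups = {s: ("control" if s.startswith("C") else "treated") for s in samples}
    base_ct = pd.Series(
        rng.normal(base_ct_mean, base_ct_sd, size=n_mirna), index=assays
    )
    data = {}
    for s in samples:
        mu = base_ct.copy()
        if groups[s] == "treated":
            for m, signed_fc in fc_map.items():
                ratio = signed_fc if signed_fc >= 1 else -1.0 / signed_fc
                mu[m] = mu[m] - math.log2(ratio)
        noise = rng.normal(0.0, ct_sd, size=n_mirna) if ct_sd > 0 else 0.0
        data[s] = mu + noise
    ct = pd.DataFrame(data, index=assays)
    ct = ct.mask(ct > dropout_ct_threshold)
    return ct, groups, base_ct
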