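"""Cross-platform (sequencing vs qPCR) miRNA concordance.

The two platforms name miRNAs differently (qPCR assays are designed
against an older catalogue), so identifiers are first harmonized to
canonical ids -- by an explicit assay-sequence :class:`~urimir.refio.IDMap`
when available, or taken as already canonical.  The report covers
detection-consistency tables (percent of detected miRNAs seen in exactly
k samples), detection-set overlap, and the intersection of
significantly-changed sets with per-miRNA direction agreement.

The published significant sets from the study this pipeline models ship
as packaged fixtures (one per platform) and are the canonical worked
example: their harmonized intersection has exactly three members --
rno-let-7d-5p, rno-miR-203a-3p and rno-miR-320-3p -- all
direction-concordant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .refio import IDMap

logger = logging.getLogger(__name__)


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("urimir.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_qpcr_significant() -> pd.DataFrame:
    """Packaged fixture: the 32 qPCR-significant miRNAs (id, p, signed FC, sequence)."""
    return _load_fixture("table1_qpcr_significant.tsv")


def load_ngs_significant() -> pd.DataFrame:
    """Packaged fixture: the 14 sequencing-significant miRNAs."""
    return _load_fixture("table4_ngs_significant.tsv")


@dataclass
class HarmonizedSets:
    universe: set[str]
    members_a: set[str]
    members_b: set[str]
    unmapped_a: list[str] = field(default_factory=list)
    unmapped_b: list[str] = field(default_factory=list)

    @property
    def both(self) -> set[str]:
        return self.members_a & self.members_b

    @property
    def only_a(self) -> set[str]:
        return self.members_a - self.members_b

    @property
    def only_b(self) -> set[str]:
        return self.members_b - self.members_a


def harmonize(
    platform_a_ids,
    platform_b_ids,
    idmap_a: IDMap | None = None,
    idmap_b: IDMap | None = None,
) -> HarmonizedSets:
    """Express both platforms in canonical ids.

    Ids with an idmap are translated; ids without one are taken as already
    canonical.  Unmapped assay ids go to a side list (excluded from the
    overlap arithmetic, never dropped silently).  Ids differing only by
    the -5p/-3p arm suffix are distinct miRNAs and are never merged.
    """

    def _translate(ids, idmap: IDMap | None):
        members, unmapped = set(), []
        for i in ids:
            if idmap is None:
                members.add(i)
            else:
                canon = idmap.translate(i)
                if canon is None:
                    unmapped.append(i)
                else:
                    members.add(canon)
        return members, unmapped

    members_a, unmapped_a = _translate(platform_a_ids, idmap_a)
    members_b, unmapped_b = _translate(platform_b_ids, idmap_b)
    if unmapped_a or unmapped_b:
        logger.info(
            "unmapped assay ids: %d platform A, %d platform B",
            len(unmapped_a),
            len(unmapped_b),
        )
    return HarmonizedSets(
        universe=members_a | members_b,
        members_a=members_a,
        members_b=members_b,
        unmapped_a=unmapped_a,
        unmapped_b=unmapped_b,
    )


def consistency_table(detection: pd.DataFrame, digits: int = 2) -> pd.Series:
    """Percent of detected miRNAs detected in exactly k samples, k = 1..n.

    The denominator is the number of miRNAs detected in at least one
    sample; columns sum to 100 within rounding.
    """
    per_row = detection.sum(axis=1)
    denom = int((per_row >= 1).sum())
    n = detection.shape[1]
    if denom == 0:
        logger.warning("no detections; empty consistency table")
        return pd.Series(dtype=float, name="percent")
    pct = {
        k: round(100.0 * int((per_row == k).sum()) / denom, digits)
        for k in range(1, n + 1)
    }
    return pd.Series(pct, name="percent")


@dataclass
class OverlapRecord:
    mirna_id: str
    fc_a: float
    fc_b: float
    direction_agreement: bool


def overlap_significant(
    sig_a: pd.DataFrame,
    sig_b: pd.DataFrame,
    idmap_a: IDMap | None = None,
    idmap_b: IDMap | None = None,
    id_col: str = "mirna_id",
    fc_col: str = "fc_signed",
) -> list[OverlapRecord]:
    """Intersection of two significant sets by canonical id with per-miRNA
    direction-agreement flags (sign of the signed FC must match; a
    boundary FC of exactly +1 agrees with nothing)."""

    def _fc_by_canon(df: pd.DataFrame, idmap: IDMap | None) -> dict[str, float]:
        out = {}
        for _, row in df.iterrows():
            canon = row[id_col] if idmap is None else idmap.translate(row[id_col])
            if canon is not None:
                out[canon] = float(row[fc_col])
        return out

    fc_a = _fc_by_canon(sig_a, idmap_a)
    fc_b = _fc_by_canon(sig_b, idmap_b)
    records = []
    for mid in sorted(set(fc_a) & set(fc_b)):
        a, b = fc_a[mid], fc_b[mid]
        agree = abs(a) > 1 and abs(b) > 1 and (a > 0) == (b > 0)
        records.append(OverlapRecord(mid, a, b, agree))
    return records


def concordance_report(
    sig_a: pd.DataFrame,
    sig_b: pd.DataFrame,
    detection_a: pd.DataFrame | None = None,
    detection_b: pd.DataFrame | None = None,
    **overlap_kwargs,
) -> dict:
    """JSON-ready cross-platform summary."""
    overlap = overlap_significant(sig_a, sig_b, **overlap_kwargs)
    sets = harmonize(
        sig_a["mirna_id"],
        sig_b["mirna_id"],
        overlap_kwargs.get("idmap_a"),
        overlap_kwargs.get("idmap_b"),
    )
    report = {
        "significant_a": len(sets.members_a),
        "significant_b": len(sets.members_b),
        "significant_both": len(sets.both),
        "significant_only_a": len(sets.only_a),
        "significant_only_b": len(sets.only_b),
        "intersection": [
            {
                "mirna_id": r.mirna_id,
                "fc_a": r.fc_a,
                "fc_b": r.fc_b,
                "direction_agreement": r.direction_agreement,
            }
            for r in overlap
        ],
    }
    if detection_a is not None:
        report["consistency_a"] = consistency_table(detection_a).to_dict()
    if detection_b is not None:
        report["consistency_b"] = consistency_table(detection_b).to_dict()
    return report
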