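"""TLDA-style qPCR Ct pipeline: parsing, detection filtering, normalization
(global mean / invariant set / lowess) and ΔΔCt fold changes.

Ct is the threshold cycle: lower Ct means more template, and a true
expression ratio r between groups shifts the treated mean Ct by -log2(r).
"Undetermined" wells are missing data (never imputed): the detection
filter -- Ct <= 32 in at least 20% of samples -- already encodes
detectability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .stats import DEResult, signed_fold_change, welch_test

logger = logging.getLogger(__name__)

UNDETERMINED = "Undetermined"


def read_ct_csv(path) -> pd.DataFrame:
    """Ct CSV: first column assay id, remaining columns samples; the literal
    ``Undetermined`` becomes NaN."""
    df = pd.read_csv(path, index_col=0)
    df = df.apply(lambda col: pd.to_numeric(col.replace(UNDETERMINED, np.nan), errors="raise"))
    return df


def write_ct_csv(ct: pd.DataFrame, path) -> None:
    out = ct.round(4).astype(object).where(ct.notna(), UNDETERMINED)
    out.to_csv(path)


def load_group_map(path) -> dict[str, str]:
    """Two-column TSV: sample_id <tab> group."""
    groups = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.lower().startswith("sample"):
                continue
            sample, group = line.split("\t")[:2]
            groups[sample] = group
    return groups


def ct_detection_filter(
    ct: pd.DataFrame, max_ct: float = 32.0, min_fraction: float = 0.20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep assays detected (Ct present and <= max_ct) in at least
    ceil(min_fraction * n_samples) samples."""
    if ct.empty:
        raise ValueError("empty Ct matrix")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    detected = ct.notna() & (ct <= max_ct)
    need = math.ceil(min_fraction * ct.shape[1])
    keep = detected.sum(axis=1) >= need
    return ct.loc[keep], detected


def _global_mean_offsets(ct: pd.DataFrame) -> pd.Series:
    col_means = ct.mean(axis=0, skipna=True)
    return col_means - col_means.mean()


def normalize_ct(
    ct: pd.DataFrame,
    method: str = "global_mean",
    lowess_span: float = 0.5,
    invariant_k: int = 10,
) -> pd.DataFrame:
    """Normalize a (filtered) Ct matrix.

    * ``global_mean`` — subtract each sample's mean detected Ct, add back
      the grand mean.
    * ``invariant`` — same offset removal, but offsets estimated from the
      ``invariant_k`` complete-case assays with the lowest across-sample
      Ct variance.
    * ``lowess`` — per sample, a locally weighted regression of
      (sample Ct - reference Ct) on reference Ct is fitted and subtracted,
      where the reference is the per-assay mean profile (cyclic-to-reference
      lowess; span ``lowess_span``, 3 robustness iterations).
    """
    if method == "global_mean":
        offsets = _global_mean_offsets(ct)
        return ct.sub(offsets, axis=1)
    if method == "invariant":
        complete = ct.dropna(axis=0)
        if complete.shape[0] < invariant_k:
            logger.warning(
                "only %d complete-case assays (< invariant_k=%d); using all",
                complete.shape[0],
                invariant_k,
            )
            chosen = complete
        else:
            variances = complete.var(axis=1)
            chosen = complete.loc[variances.nsmallest(invariant_k).index]
        if chosen.empty:
            raise ValueError("no complete-case assays to estimate invariant offsets")
        col_means = chosen.mean(axis=0)
        offsets = col_means - col_means.mean()
        return ct.sub(offsets, axis=1)
    if method == "lowess":
        reference = ct.mean(axis=1, skipna=True)
        out = ct.copy()
        for sample in ct.columns:
            present = ct[sample].notna() & reference.notna()
            if present.sum() < 3:
                continue
            x = reference[present].to_numpy()
            y = (ct.loc[present, sample] - reference[present]).to_numpy()
            fitted = sm_lowess(
                y, x, frac=lowess_span, it=3, return_sorted=False
            )
            out.loc[present, sample] = ct.loc[present, sample] - fitted
        return out
    raise ValueError(f"unknown Ct normalization method {method!r}")


@dataclass
class NotTestable:
    assay_id: str
    reason: str


def ct_fold_change(
    ct: pd.DataFrame,
    groups: dict[str, str],
    control: str = "control",
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    min_per_group: int = 2,
) -> tuple[list[DEResult], list[NotTestable]]:
    """ΔΔCt fold change + Welch p per assay.

    ΔΔCt = mean Ct(treated) - mean Ct(control); ratio = 2^(-ΔΔCt); the
    Welch test runs on the per-sample (normalized) Ct values.  Assays with
    fewer than `min_per_group` detected values in either group are
    reported as not-testable.
    """
    levels = sorted(set(groups.values()))
    if len(levels) != 2 or control not in levels:
        raise ValueError("groups must define exactly two levels incl. the control")
    treated = [g for g in levels if g != control][0]
    cols_c = [s for s in ct.columns if groups.get(s) == control]
    cols_t = [s for s in ct.columns if groups.get(s) == treated]
    results: list[DEResult] = []
    skipped: list[NotTestable] = []
    for assay, row in ct.iterrows():
        c = row[cols_c].dropna().to_numpy(dtype=float)
        t = row[cols_t].dropna().to_numpy(dtype=float)
        if len(c) < min_per_group or len(t) < min_per_group:
            skipped.append(
                NotTestable(str(assay), f"detected in {len(c)} control / {len(t)} treated")
            )
            continue
        ddct = t.mean() - c.mean()
        ratio = 2.0 ** (-ddct)
        fc = signed_fold_change(ratio)
        _, _, p = welch_test(c, t)
        significant = bool(p < p_threshold and abs(fc) >= fc_threshold)
        results.append(DEResult(str(assay), float(fc), float(p), "welch_ct", significant))
    return results, skipped
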