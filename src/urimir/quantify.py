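"""Count matrices and the three normalizations compared in the pipeline.

Counts are merged per miRNA across all isomiR categories before
normalization.  The three methods, each implemented from its defining
formula:

* **RPM** — reads per million miRNA-mapped reads:
  ``v_ij = k_ij / sum_i k_ij * 1e6``.
* **Median-of-ratios size factors** — ``s_j = median_i k_ij / g_i`` over
  rows i whose geometric mean ``g_i = (prod_v k_iv)^(1/m)`` is positive.
* **TMM** — weighted trimmed mean of M-values against a reference sample:
  ``M_i = log2((k_ij/N_j)/(k_ir/N_r))``, ``A_i = 0.5*log2(k_ij*k_ir/(N_j*N_r))``,
  doubly trimmed (30% on M, 5% on A) and weighted by the inverse binomial
  variance approximation, then rescaled so factors have geometric mean 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def build_count_matrix(profiles) -> pd.DataFrame:
    """miRNA x sample integer counts from per-sample classification profiles.

    Column sums equal each sample's miRNA-mapped totals (isomiR categories
    merged per miRNA).
    """
    columns = {}
    for profile in profiles:
        columns[profile.sample_id] = profile.merged_counts()
    df = pd.DataFrame(columns).fillna(0).astype(int)
    return df.sort_index()


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame
    method: str
    scale_factors: pd.Series


def rpm_normalize(counts: pd.DataFrame) -> NormalizedMatrix:
    """Reads-per-million columns; an all-zero column stays zero with a warning."""
    totals = counts.sum(axis=0).astype(float)
    if (totals == 0).all():
        raise ValueError("all columns are zero")
    if (totals == 0).any():
        logger.warning(
            "all-zero columns left as zero: %s", list(totals.index[totals == 0])
        )
    safe = totals.replace(0, np.nan)
    values = counts.div(safe, axis=1).mul(1e6).fillna(0.0)
    return NormalizedMatrix(values=values, method="rpm", scale_factors=totals / 1e6)


def size_factors_median_ratio(counts: pd.DataFrame, pseudo_count: float = 0.0) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style scaling).

    Requires at least one row with an all-positive geometric mean; the
    optional pseudo-count rescues degenerate fixtures.
    """
    mat = counts.to_numpy(dtype=float) + pseudo_count
    with np.errstate(divide="ignore"):
        log_geo = np.log(mat).mean(axis=1)
    usable = np.isfinite(log_geo)
    if not usable.any():
        raise ValueError(
            "no row has a positive geometric mean; consider pseudo_count=0.5"
        )
    ratios = mat[usable] / np.exp(log_geo[usable])[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def size_factor_normalize(counts: pd.DataFrame, pseudo_count: float = 0.0) -> NormalizedMatrix:
    s = size_factors_median_ratio(counts, pseudo_count)
    return NormalizedMatrix(values=counts / s, method="size_factor", scale_factors=s)


def _choose_reference(counts: pd.DataFrame) -> str:
    """Sample whose 75th-percentile count fraction is closest to the mean."""
    frac = counts.div(counts.sum(axis=0), axis=1)
    q75 = frac.quantile(0.75, axis=0)
    return (q75 - q75.mean()).abs().idxmin()


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM scale factors, geometric mean 1.

    A sample sharing no positive rows with the reference gets factor 1
    with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    if ref_sample is None:
        ref_sample = _choose_reference(counts)
    totals = counts.sum(axis=0).astype(float)
    kr = counts[ref_sample].to_numpy(dtype=float)
    nr = totals[ref_sample]
    log_factors = {}
    for sample in counts.columns:
        if sample == ref_sample:
            log_factors[sample] = 0.0
            continue
        kj = counts[sample].to_numpy(dtype=float)
        nj = totals[sample]
        mask = (kj > 0) & (kr > 0)
        if not mask.any():
            logger.warning("no co-positive rows between %s and reference; factor 1", sample)
            log_factors[sample] = 0.0
            continue
        a_j, a_r = kj[mask], kr[mask]
        m = np.log2((a_j / nj) / (a_r / nr))
        a = 0.5 * np.log2((a_j / nj) * (a_r / nr))
        w = (nj - a_j) / (nj * a_j) + (nr - a_r) / (nr * a_r)
        n = len(m)
        keep = np.ones(n, dtype=bool)
        for stat, trim in ((m, trim_m), (a, trim_a)):
            k_cut = int(np.floor(n * trim))
            order = np.argsort(stat, kind="stable")
            if k_cut > 0:
                keep[order[:k_cut]] = False
                keep[order[n - k_cut :]] = False
        if not keep.any() or w[keep].sum() == 0:
            log_factors[sample] = 0.0
            continue
        # inverse-variance weights: w above approximates var(M); weight = 1/var
        inv_w = 1.0 / w[keep]
        log_factors[sample] = float(np.sum(inv_w * m[keep]) / np.sum(inv_w))
    s = pd.Series({k: 2.0**v for k, v in log_factors.items()}, name="tmm_factor")
    s = s / np.exp(np.log(s).mean())  # rescale to geometric mean 1
    return s.reindex(counts.columns)


def tmm_normalize(counts: pd.DataFrame, **kwargs) -> NormalizedMatrix:
    """Counts scaled by effective library size (library total x TMM factor),
    per million."""
    s = tmm_factors(counts, **kwargs)
    eff = counts.sum(axis=0) * s
    values = counts.div(eff, axis=1).mul(1e6)
    return NormalizedMatrix(values=values, method="tmm", scale_factors=s)


def normalize(counts: pd.DataFrame, method: str, **kwargs) -> NormalizedMatrix:
    """Dispatch on method tag in {rpm, size_factor, tmm}."""
    if method == "rpm":
        return rpm_normalize(counts)
    if method == "size_factor":
        return size_factor_normalize(counts, **kwargs)
    if method == "tmm":
        return tmm_normalize(counts, **kwargs)
    raise ValueError(f"unknown normalization method {method!r}")
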