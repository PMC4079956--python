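"""Detection filtering, Spearman/complete-linkage clustering and
differential expression with the study thresholds (p < 0.05, |FC| >= 1.5).

Fold changes use the symmetric signed convention: a ratio r >= 1 is
reported as +r, a ratio r < 1 as -1/r, so magnitudes are comparable
around +/-1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


def signed_fold_change(ratio: float) -> float:
    """Encode a positive ratio on the signed scale: r>=1 -> +r, r<1 -> -1/r."""
    if not ratio > 0:
        raise ValueError(f"ratio must be positive, got {ratio}")
    return ratio if ratio >= 1 else -1.0 / ratio


def decode_signed_fold_change(fc: float) -> float:
    """Inverse of :func:`signed_fold_change` (|fc| must be >= 1)."""
    if abs(fc) < 1:
        raise ValueError(f"signed fold change must have magnitude >= 1, got {fc}")
    return fc if fc >= 0 else -1.0 / fc


@dataclass(frozen=True)
class DEResult:
    mirna_id: str
    fc_signed: float
    p_value: float
    test: str
    significant: bool


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in results])
    if df.empty:
        return pd.DataFrame(
            columns=["mirna_id", "fc_signed", "p_value", "test", "significant"]
        )
    # volcano-plot-ready columns
    df["log2_fc"] = np.sign(df["fc_signed"]) * np.log2(df["fc_signed"].abs())
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p_value"])
    return df


def detection_filter(matrix: pd.DataFrame, min_samples: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows detected (count > 0) in fewer than `min_samples` samples.

    Returns (filtered matrix, boolean detection matrix for the kept input).
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    if min_samples > matrix.shape[1]:
        raise ValueError(
            f"min_samples {min_samples} exceeds sample count {matrix.shape[1]}"
        )
    detected = matrix > 0
    keep = detected.sum(axis=1) >= min_samples
    return matrix.loc[keep], detected


@dataclass
class ClusterResult:
    distance: pd.DataFrame  # 1 - Spearman rho, samples x samples
    linkage: np.ndarray  # scipy linkage records (complete)
    leaf_order: list[str]

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.distance.index, labels))


def spearman_complete_cluster(matrix: pd.DataFrame) -> ClusterResult:
    """Agglomerate samples by complete linkage on d = 1 - Spearman rho.

    Columns are sorted lexicographically first so ties break
    deterministically; a constant column (zero rank variance) gets rho = 0
    against everything, with a warning.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 rows and 2 samples")
    matrix = matrix[sorted(matrix.columns)]
    # Spearman rho = Pearson correlation of average ranks, column-wise
    ranks = np.apply_along_axis(sps.rankdata, 0, matrix.to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    if np.isnan(rho).any():
        logger.warning("constant column(s): undefined Spearman rho set to 0")
        rho = np.where(np.isnan(rho), 0.0, rho)
    np.fill_diagonal(rho, 1.0)
    dist = 1.0 - rho
    dist = (dist + dist.T) / 2  # enforce exact symmetry
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    order = [matrix.columns[i] for i in hierarchy.leaves_list(z)]
    return ClusterResult(
        distance=pd.DataFrame(dist, index=matrix.columns, columns=matrix.columns),
        linkage=z,
        leaf_order=order,
    )


def welch_test(group_a, group_b) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Welch-Satterthwaite df, two-sided p).

    Degenerate zero-variance inputs follow the limiting behaviour: equal
    means -> p = 1; unequal means -> p = 0 (with a warning).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0
        logger.warning("zero variance with unequal means: p = 0")
        return math.copysign(math.inf, diff), float(na + nb - 2), 0.0
    t = diff / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def exact_count_test(
    count_a: int, count_b: int, depth_a: float, depth_b: float
) -> float:
    """Two-sided conditional binomial test on pooled counts.

    Conditional on the total K = count_a + count_b, count_a is
    Binomial(K, depth_a/(depth_a+depth_b)) under the null; the two-sided
    p-value sums outcome probabilities <= the observed one.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("depths must be positive")
    total = count_a + count_b
    if total == 0:
        return 1.0
    p0 = depth_a / (depth_a + depth_b)
    return float(sps.binomtest(count_a, total, p0, alternative="two-sided").pvalue)


def differential_expression(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    method: str = "welch_log",
    p_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    scale_factors: pd.Series | None = None,
    control: str | None = None,
    log_pseudo: float = 1.0,
) -> list[DEResult]:
    """Per-miRNA signed fold change and p-value between two groups.

    FC = mean(treated)/mean(control) on the linear normalized scale.
    ``welch_log`` tests log2(v + log_pseudo) values; ``exact_count``
    expects raw counts and pools them per group with depths proportional
    to the per-sample scale factors (library totals by default).
    """
    unknown = set(groups) - set(matrix.columns)
    if unknown:
        raise ValueError(f"unknown samples in groups: {sorted(unknown)}")
    levels = sorted(set(groups.values()))
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    ctrl = control if control is not None else levels[0]
    trt = [g for g in levels if g != ctrl][0]
    cols_a = [s for s, g in groups.items() if g == ctrl]
    cols_b = [s for s, g in groups.items() if g == trt]
    if method == "welch_log" and (len(cols_a) < 2 or len(cols_b) < 2):
        raise ValueError("welch_log needs >= 2 samples per group")
    if scale_factors is None:
        scale_factors = matrix.sum(axis=0).astype(float)
    results: list[DEResult] = []
    for mirna_id, row in matrix.iterrows():
        a = row[cols_a].to_numpy(dtype=float)
        b = row[cols_b].to_numpy(dtype=float)
        mean_a, mean_b = a.mean(), b.mean()
        if mean_a == 0 and mean_b == 0:
            fc, p = 1.0, 1.0
        else:
            ratio = math.inf if mean_a == 0 else mean_b / mean_a
            if method == "welch_log":
                _, _, p = welch_test(
                    np.log2(a + log_pseudo), np.log2(b + log_pseudo)
                )
            elif method == "exact_count":
                p = exact_count_test(
                    int(round(b.sum())),
                    int(round(a.sum())),
                    float(scale_factors[cols_b].sum()),
                    float(scale_factors[cols_a].sum()),
                )
            else:
                raise ValueError(f"unknown DE method {method!r}")
            fc = signed_fold_change(ratio) if math.isfinite(ratio) else math.inf
        significant = bool(p < p_threshold and abs(fc) >= fc_threshold)
        results.append(DEResult(str(mirna_id), float(fc), float(p), method, significant))
    return results


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p is the default criterion)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
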