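"""Quantitative evaluation: confusion, correlation, ROC/AUC, cohorts.

Accuracy confidence intervals are exact binomial (Clopper–Pearson),
Pearson intervals use the Fisher z-transform, AUC uses the rank
(Mann-Whitney) formulation with the DeLong covariance estimator for
intervals and paired comparisons, and cohort maps are per-pixel medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ImageGrid, LabelField


# ---------------------------------------------------------------------------
# segmentation confusion
# ---------------------------------------------------------------------------

@dataclass
class ConfusionResult:
    labels: tuple[str, ...]
    counts: pd.DataFrame  # rows = truth, columns = prediction
    per_mille: pd.DataFrame  # 1000 * count / N, half-up rounded to integer
    n: int
    accuracy: float
    ci: tuple[float, float]


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def _half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(int)


def accuracy_from_counts(matrix: np.ndarray) -> float:
    """Overall accuracy (diagonal mass / total) of a square count matrix."""
    m = np.asarray(matrix, dtype=float)
    return float(np.trace(m) / m.sum())


def accuracy_from_permille(matrix: np.ndarray) -> float:
    """Overall accuracy of a printed per-mille confusion matrix.

    Rounded per-mille entries need not sum to exactly 1000, so the
    diagonal is taken against the nominal 1000 rather than the table sum.
    """
    return float(np.trace(np.asarray(matrix, dtype=float)) / 1000.0)


def confusion(
    truth: LabelField,
    pred: LabelField,
    exclude: set[str] = frozenset({"BG"}),
) -> ConfusionResult:
    """Confusion matrix of two label fields over non-excluded pixels.

    Rows are truth, columns prediction; per-mille entries are
    1000·count/N rounded half-up; the accuracy CI is exact binomial.
    """
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    names = [n for n in truth.label_set if n not in exclude]
    t = truth.labels.ravel()
    p = pred.labels.ravel()
    keep = np.isin(t, [truth.index(n) for n in names]) & np.isin(
        p, [pred.index(n) for n in names if n in pred.label_set]
    )
    counts = np.zeros((len(names), len(names)), dtype=int)
    for i, tn in enumerate(names):
        for j, pn in enumerate(names):
            counts[i, j] = np.sum(
                keep & (t == truth.index(tn)) & (p == pred.index(pn))
            )
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no pixels left after exclusion")
    acc = float(np.trace(counts) / n)
    per_mille = _half_up(1000.0 * counts / n)
    return ConfusionResult(
        labels=tuple(names),
        counts=pd.DataFrame(counts, index=names, columns=names),
        per_mille=pd.DataFrame(per_mille, index=names, columns=names),
        n=n,
        accuracy=acc,
        ci=_clopper_pearson(int(np.trace(counts)), n),
    )


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_ci(
    x: np.ndarray,
    y: np.ndarray,
    exclude_mask: np.ndarray | None = None,
    level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Pearson r with a Fisher-z confidence interval.

    ``exclude_mask`` marks pixels to drop (e.g. background members).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if exclude_mask is not None:
        keep = ~np.asarray(exclude_mask, dtype=bool).ravel()
        x, y = x[keep], y[keep]
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError("need at least 4 paired values")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance input")
    r = float(stats.pearsonr(x, y).statistic)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(x.size - 3)
    zc = stats.norm.ppf(0.5 + level / 2)
    return r, (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong intervals
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, truth: np.ndarray):
    """AUC and the DeLong structural components (V10, V01)."""
    pos = scores[truth]
    neg = scores[~truth]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v10, v01


def roc_auc(
    scores: np.ndarray, binary_truth: np.ndarray, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """AUC (midrank Mann-Whitney formulation) with a DeLong interval."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(binary_truth, dtype=bool).ravel()
    auc, v10, v01 = _delong_components(scores, truth)
    var = np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size
    zc = stats.norm.ppf(0.5 + level / 2)
    half = zc * np.sqrt(max(var, 0.0))
    return auc, (float(max(auc - half, 0.0)), float(min(auc + half, 1.0)))


def compare_auc(
    scores_a: np.ndarray, scores_b: np.ndarray, binary_truth: np.ndarray
) -> tuple[float, float]:
    """DeLong paired test of two correlated AUCs; returns (z, p)."""
    truth = np.asarray(binary_truth, dtype=bool).ravel()
    auc_a, v10a, v01a = _delong_components(np.asarray(scores_a).ravel(), truth)
    auc_b, v10b, v01b = _delong_components(np.asarray(scores_b).ravel(), truth)
    s10 = np.cov(np.stack([v10a, v10b]))
    s01 = np.cov(np.stack([v01a, v01b]))
    var = (
        s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]
    ) / v10a.size + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / v01a.size
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# cohorts and rank tests
# ---------------------------------------------------------------------------

def cohort_median_map(aligned_images: list[ImageGrid]) -> ImageGrid:
    """Per-pixel median across co-registered images; masks intersect."""
    if not aligned_images:
        raise ValueError("need at least one image")
    shapes = {g.shape for g in aligned_images}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch across images: {shapes}")
    stack = np.stack([g.values for g in aligned_images])
    mask = np.logical_and.reduce([g.mask for g in aligned_images])
    return ImageGrid(np.median(stack, axis=0), mask)


def mannwhitney(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p-value.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise; fully tied degenerate inputs give p = 1.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 12) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
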