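"""Unsupervised metric learning: from GMRF residuals to histology units.

Each tissue pixel gets a triple of Mahalanobis distances (d_WM, d_GM,
d_CB) — precision-scaled squared residuals of the pixel under each
tissue's GMRF conditional. Per-tissue means of these triples are the MRI
landmarks; the histology landmarks are the per-tissue (myelin,
cellularity) staining means. A per-channel scale fitted by Nelder-Mead
aligns the two metric spaces, and numerical multilateration against the
histology anchors maps every pixel into (myelin, cellularity) units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .core import BG, ImageGrid, LabelField
from .gmrf import GMRFModel, _pair_sums

#: Default histology-side landmarks, per-tissue (myelin=blue, cellularity=red)
#: staining means; usable when no study-specific histology GMM is available.
DEFAULT_HIST_LANDMARKS = {
    "WM": (0.735, 0.230),
    "GM": (0.333, 0.666),
    "CB": (0.341, 0.785),
}

TISSUES = ("WM", "GM", "CB")

_NM_OPTIONS = {"xatol": 1e-6, "fatol": 1e-6, "maxfev": 2000}


@dataclass
class MetricSpace:
    """Landmarks and scales tying the MRI distance space to histology."""

    mri_landmarks: dict[str, np.ndarray]  # tissue -> (d_WM, d_GM, d_CB)
    hist_landmarks: dict[str, np.ndarray]  # tissue -> (myelin, cellularity)
    scales: np.ndarray  # (3,) positive multipliers per distance channel


@dataclass
class FeatureMap:
    """Per-pixel (myelin, cellularity) estimates; NaN outside the tissue."""

    myelin: np.ndarray
    cellularity: np.ndarray
    space: MetricSpace


def mahalanobis_distance(
    i: tuple[int, int],
    tissue: str,
    image: ImageGrid,
    labels: LabelField,
    model: GMRFModel,
) -> float:
    """Squared precision-scaled residual of one pixel from one tissue.

    d_il = ((x_i - mu_l) - sum_j beta_lj (x_j - mu_j))^2 / beta00_l,
    with neighbour means taken from each neighbour's current label and
    background neighbours excluded.
    """
    return float(mahalanobis_map(image, labels, model, tissue)[i])


def mahalanobis_map(
    image: ImageGrid,
    labels: LabelField,
    model: GMRFModel,
    tissue: str,
) -> np.ndarray:
    """Whole-grid Mahalanobis distance to one tissue's GMRF mean."""
    if tissue == BG:
        raise ValueError("Mahalanobis distance to BG is undefined")
    p = model.params[tissue]
    mu_map = model.mu_array()[labels.labels]
    valid = image.mask & (labels.labels != labels.bg_index)
    sums = _pair_sums(image.values, mu_map, valid, model.neighborhood)
    resid = (image.values - p.mu) - np.tensordot(p.beta, sums, axes=(0, 0))
    return resid**2 / p.beta00


def mri_tissue_landmarks(
    dmaps: dict[str, np.ndarray], labels: LabelField
) -> dict[str, np.ndarray]:
    """Per-tissue mean of the (d_WM, d_GM, d_CB) triple over its pixels."""
    out = {}
    for tissue in TISSUES:
        sel = labels.of(tissue)
        if not sel.any():
            raise ValueError(f"no pixels labelled {tissue}")
        out[tissue] = np.array([dmaps[c][sel].mean() for c in TISSUES])
    return out


def _hist_distance_triples(
    hist_landmarks: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Inter-landmark Euclidean distances implied by histology positions."""
    h = {t: np.asarray(hist_landmarks[t], dtype=float) for t in TISSUES}
    return {
        t: np.array([np.linalg.norm(h[t] - h[c]) for c in TISSUES])
        for t in TISSUES
    }


def fit_scales(
    mri_landmarks: dict[str, np.ndarray],
    hist_landmarks: dict[str, np.ndarray],
) -> np.ndarray:
    """Per-channel scales aligning MRI distance triples with histology.

    Nelder-Mead minimizes the RMS mismatch between the scaled MRI
    tissue-mean triples and the inter-landmark distances implied by the
    histology positions; deterministic (fixed start at (1,1,1), one
    restart from the optimum).
    """
    if len(mri_landmarks) < 3 or len(hist_landmarks) < 3:
        raise ValueError("at least 3 landmarks required on both sides")
    mri = np.stack([np.asarray(mri_landmarks[t], float) for t in TISSUES])
    hist = np.stack([_hist_distance_triples(hist_landmarks)[t] for t in TISSUES])

    def objective(s: np.ndarray) -> float:
        return float(np.sqrt(np.mean((mri * s[None, :] - hist) ** 2)))

    res = minimize(objective, np.ones(3), method="Nelder-Mead", options=_NM_OPTIONS)
    res = minimize(objective, res.x, method="Nelder-Mead", options=_NM_OPTIONS)
    if not res.success and res.fun > objective(np.ones(3)):
        raise RuntimeError(f"scale optimization failed to converge: {res.message}")
    return res.x


def multilaterate(
    scaled_distances: np.ndarray,
    anchors: np.ndarray,
) -> np.ndarray:
    """Planar position whose anchor distances best match the given ones.

    Minimizes sum_l (||p - anchor_l|| - d_l)^2 by Nelder-Mead from the
    anchor centroid. Anchors must not be collinear. Anchor order is
    irrelevant (pairs are sorted internally for exact symmetry).
    """
    d = np.asarray(scaled_distances, dtype=float)
    a = np.asarray(anchors, dtype=float)
    if a.shape != (3, 2) or d.shape != (3,):
        raise ValueError("expected 3 planar anchors and 3 distances")
    u, v = a[1] - a[0], a[2] - a[0]
    area2 = abs(u[0] * v[1] - u[1] * v[0])
    scale = max(np.abs(a).max(), 1.0)
    if area2 < 1e-9 * scale**2:
        raise ValueError("anchors are collinear; multilateration is degenerate")
    order = np.lexsort((a[:, 1], a[:, 0]))
    a, d = a[order], d[order]

    def objective(p: np.ndarray) -> float:
        return float(np.sum((np.linalg.norm(a - p[None, :], axis=1) - d) ** 2))

    p0 = a.mean(axis=0)
    res = minimize(objective, p0, method="Nelder-Mead", options=_NM_OPTIONS)
    res = minimize(objective, res.x, method="Nelder-Mead", options=_NM_OPTIONS)
    return res.x


def feature_maps(
    image: ImageGrid,
    labels: LabelField,
    model: GMRFModel,
    hist_landmarks: dict[str, tuple[float, float]] | None = None,
    squared: bool = True,
) -> FeatureMap:
    """Per-pixel (myelin, cellularity) estimates from GMRF residuals.

    Computes the (d_WM, d_GM, d_CB) triple per tissue pixel (PV included,
    BG excluded), fits the channel scales against the histology
    landmarks, and multilaterates each pixel into histology units.
    ``squared=False`` feeds the square root of the Mahalanobis quantity
    to multilateration instead (sensitivity variant).
    """
    hist = {
        t: np.asarray(v, dtype=float)
        for t, v in (hist_landmarks or DEFAULT_HIST_LANDMARKS).items()
    }
    for t in TISSUES:
        if t not in labels.label_set:
            raise ValueError(f"label set must contain {t}")
    dmaps = {t: mahalanobis_map(image, labels, model, t) for t in TISSUES}
    if not squared:
        dmaps = {t: np.sqrt(m) for t, m in dmaps.items()}
    mri_lm = mri_tissue_landmarks(dmaps, labels)
    scales = fit_scales(mri_lm, hist)
    space = MetricSpace(mri_lm, hist, scales)

    anchors = np.stack([hist[t] for t in TISSUES])
    tissue_sel = image.mask & (labels.labels != labels.bg_index)
    myelin = np.full(image.shape, np.nan)
    cellularity = np.full(image.shape, np.nan)
    triples = np.stack([dmaps[t] for t in TISSUES], axis=-1) * scales[None, None, :]
    cache: dict[tuple, np.ndarray] = {}
    for i, j in zip(*np.nonzero(tissue_sel)):
        key = tuple(np.round(triples[i, j], 12))
        pos = cache.get(key)
        if pos is None:
            pos = multilaterate(triples[i, j], anchors)
            cache[key] = pos
        myelin[i, j] = pos[0]
        cellularity[i, j] = pos[1]
    return FeatureMap(myelin, cellularity, space)
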