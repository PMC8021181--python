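"""Gaussian-mixture segmentation with BIC model selection.

GMMs serve two roles: segmenting the (blue, red) histology densities into
BG/WM/GM/CB to provide ground truth and tissue-mean landmarks, and
initializing the GMRF segmentation of MRI from T2 intensity alone with
5 labels (BG/WM/PV/GM/CB).

The fitted components carry no tissue identity; a stated mapping rule
assigns them to names. For 1D MRI fits, components sorted by ascending
mean map to [BG, WM, PV, GM, CB] — the T2 brightness ordering (background
near zero, WM dark, GM brighter, CB brightest). For 2D histology fits, BG
goes to the component nearest the background colour, WM to the highest
blue mean, CB to the highest remaining red mean, and GM to the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .core import BG, ImageGrid, LabelField

_REG_COVAR = 1e-6

#: T2 brightness ordering of the 5 MRI labels (darkest to brightest).
MRI_INTENSITY_ORDER = ("BG", "WM", "PV", "GM", "CB")


@dataclass
class GMMModel:
    """A fitted Gaussian mixture plus its BIC model-selection trace."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray  # (k, d)
    covariances: np.ndarray  # (k, d, d)
    bic: float
    bic_by_k: dict[int, float]
    _gm: GaussianMixture

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self._gm.predict_proba(x)


def fit_gmm(
    samples: np.ndarray, k_candidates: Iterable[int], seed: int = 0
) -> GMMModel:
    """EM-fit a GMM for each candidate k and keep the minimum-BIC model.

    BIC = −2·loglik + p·ln(N) with p the free-parameter count; the fit is
    deterministic given ``seed``.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    ks = sorted(set(int(k) for k in k_candidates))
    if not ks or ks[0] < 1:
        raise ValueError("k_candidates must be positive integers")
    if x.shape[0] < 10 * ks[-1]:
        raise ValueError(
            f"need at least {10 * ks[-1]} samples for max k={ks[-1]}, "
            f"got {x.shape[0]}"
        )
    if np.allclose(x.var(axis=0), 0.0):
        raise ValueError("degenerate input: all samples identical")

    best = None
    bic_by_k: dict[int, float] = {}
    for k in ks:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            reg_covar=_REG_COVAR,
            n_init=3,
            random_state=seed,
            max_iter=300,
        )
        gm.fit(x)
        if not gm.converged_:
            raise RuntimeError(f"EM failed to converge for k={k}")
        bic = float(gm.bic(x))
        bic_by_k[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    bic, k, gm = best
    return GMMModel(
        n_components=k,
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        bic=bic,
        bic_by_k=bic_by_k,
        _gm=gm,
    )


def map_components_mri(means: np.ndarray, label_names: Sequence[str]) -> list[str]:
    """Assign 1D components to labels by ascending mean (T2 ordering)."""
    order = np.argsort(means[:, 0], kind="stable")
    names = [""] * len(order)
    for rank, comp in enumerate(order):
        names[comp] = label_names[rank]
    return names


def map_components_histology(
    means: np.ndarray, background: tuple[float, float] = (0.0, 0.0)
) -> list[str]:
    """Assign (blue, red) components to BG/WM/CB/GM by staining identity."""
    k = means.shape[0]
    if k != 4:
        raise ValueError(f"histology mapping expects 4 components, got {k}")
    names = [""] * k
    remaining = set(range(k))
    bg = min(remaining, key=lambda c: np.hypot(*(means[c] - np.asarray(background))))
    names[bg] = BG
    remaining.remove(bg)
    wm = max(remaining, key=lambda c: means[c, 0])  # highest blue
    names[wm] = "WM"
    remaining.remove(wm)
    cb = max(remaining, key=lambda c: means[c, 1])  # highest red
    names[cb] = "CB"
    remaining.remove(cb)
    names[remaining.pop()] = "GM"
    return names


def segment_gmm(
    model: GMMModel,
    images: ImageGrid | Sequence[ImageGrid],
    label_names: Sequence[str],
    component_labels: Sequence[str] | None = None,
) -> LabelField:
    """Posterior-argmax segmentation of one (MRI) or two (histology) grids.

    ``component_labels`` gives the tissue name of each mixture component;
    when omitted it is derived from the mapping rule matching the input
    dimensionality. Masked-out pixels are labelled BG; posterior ties
    break toward the lower label index.
    """
    grids = [images] if isinstance(images, ImageGrid) else list(images)
    d = model.means.shape[1]
    if len(grids) != d:
        raise ValueError(f"model is {d}D but {len(grids)} image grid(s) given")
    label_names = list(label_names)
    if model.n_components != len(label_names):
        raise ValueError(
            f"{model.n_components} components cannot map onto "
            f"{len(label_names)} labels"
        )
    if component_labels is None:
        if d == 1:
            if set(label_names) == set(MRI_INTENSITY_ORDER):
                ordered = list(MRI_INTENSITY_ORDER)
            else:
                # BG darkest, remaining names in given order = ascending intensity
                ordered = ([BG] if BG in label_names else []) + [
                    n for n in label_names if n != BG
                ]
            component_labels = map_components_mri(model.means, ordered)
        elif d == 2:
            component_labels = map_components_histology(model.means)
        else:
            raise ValueError("automatic component mapping supports 1D or 2D only")
    if sorted(component_labels) != sorted(label_names):
        raise ValueError("component_labels must be a permutation of label_names")

    mask = grids[0].mask
    x = np.column_stack([g.values[mask] for g in grids])
    post = model.predict_proba(x)
    # reorder component columns into label_names order so that argmax's
    # first-occurrence rule breaks ties toward the lower label index
    col_of = {name: i for i, name in enumerate(component_labels)}
    post = post[:, [col_of[name] for name in label_names]]
    flat = np.argmax(post, axis=1)

    if BG in label_names:
        fill = label_names.index(BG)
    elif not mask.all():
        raise ValueError(
            "masked-out pixels require a BG label in label_names"
        )
    else:
        fill = 0
    labels = np.full(mask.shape, fill, dtype=np.int64)
    labels[mask] = flat
    return LabelField(labels, tuple(label_names))


# ---------------------------------------------------------------------------
# pipeline conveniences
# ---------------------------------------------------------------------------

def gmm_initialize_mri(image: ImageGrid, seed: int = 0) -> LabelField:
    """5-label GMM initialization of the GMRF from T2 intensity alone.

    Fits the mixture over the full masked frame (outside pixels are 0 and
    collapse into the BG component), maps components by the T2 brightness
    ordering, and forces out-of-mask pixels to BG.
    """
    from .core import LABELS

    values = np.where(image.mask, image.values, 0.0)
    full = ImageGrid(values, np.ones(image.shape, dtype=bool))
    model = fit_gmm(values.ravel(), [len(LABELS)], seed=seed)
    field = segment_gmm(model, full, LABELS)
    labels = field.labels.copy()
    labels[~image.mask] = field.index(BG)
    return LabelField(labels, field.label_set)


def segment_histology(
    blue: ImageGrid, red: ImageGrid, seed: int = 0
) -> tuple[LabelField, dict[str, tuple[float, float]]]:
    """4-label GMM segmentation of (blue, red) histology densities.

    Returns the label field and the per-tissue (myelin, cellularity)
    staining means used as histology-side landmarks.
    """
    names = ("CB", "GM", "WM", BG)
    x = np.column_stack([blue.values.ravel(), red.values.ravel()])
    model = fit_gmm(x, [4], seed=seed)
    full_b = ImageGrid(blue.values, np.ones(blue.shape, dtype=bool))
    full_r = ImageGrid(red.values, np.ones(red.shape, dtype=bool))
    field = segment_gmm(model, [full_b, full_r], names)
    labels = field.labels.copy()
    labels[~blue.mask] = field.index(BG)
    field = LabelField(labels, field.label_set)
    landmarks = {}
    for tissue in ("WM", "GM", "CB"):
        sel = field.of(tissue) & blue.mask
        if sel.any():
            landmarks[tissue] = (
                float(blue.values[sel].mean()),
                float(red.values[sel].mean()),
            )
    return field, landmarks
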