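"""Supervised comparators: segmentation regression and additive models.

Segmentation regression predicts the histology response per segmented
tissue label from the pixel intensity and its 10 symmetric neighbour-pair
intensity sums — median (quantile 0.5) regression under the MAE loss,
least squares with per-subject intercepts under the RMSE loss. Manual
lesion masks may override the segmentation as an extra label.

The additive model is the identity-basis (linear) case of a GAM over the
same predictors, in three nested variants: intensity only ("markov-"),
intensity + neighbour terms ("markov"), and additionally a lesion dummy
with its intensity interaction ("markov+"). Supervised models are scored
by leave-one-out cross-validation over subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import BG, ImageGrid, LabelField, NeighborhoodSystem, build_neighborhood, shift

LESION = "LES"
_MIN_LABEL_PIXELS = 30
VARIANTS = ("markov-", "markov", "markov+")


@dataclass
class Subject:
    """One training/evaluation unit: an image with aligned response."""

    subject_id: str
    image: ImageGrid
    labels: LabelField
    response: np.ndarray
    lesion_mask: np.ndarray | None = None


def pixel_features(
    image: ImageGrid, neighborhood: NeighborhoodSystem | None = None
) -> np.ndarray:
    """Per-pixel predictors: intensity plus 10 neighbour-pair sums, (H, W, 11)."""
    nbh = neighborhood or build_neighborhood(20)
    vals = np.where(image.mask, image.values, 0.0)
    inm = image.mask.astype(float)
    feats = np.empty(image.shape + (1 + nbh.n_slots,))
    feats[..., 0] = image.values
    sums = np.zeros((nbh.n_slots,) + image.shape)
    for (dy, dx), slot in zip(nbh.offsets, nbh.pair_slot):
        sums[slot] += shift(vals * inm, dy, dx)
    feats[..., 1:] = np.moveaxis(sums, 0, -1)
    return feats


def _effective_label_names(subject: Subject, use_lesion: bool) -> np.ndarray:
    names = np.array(subject.labels.label_set, dtype=object)[subject.labels.labels]
    if use_lesion:
        if subject.lesion_mask is None:
            raise ValueError(f"subject {subject.subject_id} has no lesion mask")
        names[np.asarray(subject.lesion_mask, dtype=bool)] = LESION
    return names


@dataclass
class SegRegressionModel:
    """Per-label coefficient sets mapping predictors to the response."""

    coefs: dict[str, np.ndarray]  # label -> (intercept, 11 slopes)
    loss: str
    use_lesion: bool
    neighborhood: NeighborhoodSystem = field(default_factory=build_neighborhood)


def _fit_rows(X: np.ndarray, y: np.ndarray, groups: np.ndarray, loss: str) -> np.ndarray:
    """Fit one label's rows; returns (intercept, slopes).

    MAE: median regression with a single intercept. RMSE: least squares
    with per-subject (fixed-effect) intercepts, averaged for prediction.
    """
    if loss == "mae":
        design = sm.add_constant(X, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.QuantReg(y, design).fit(q=0.5, max_iter=2000)
        return np.asarray(fit.params)
    if loss == "rmse":
        uniq = np.unique(groups)
        dummies = (groups[:, None] == uniq[None, :]).astype(float)
        design = np.hstack([dummies, X])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        intercept = coef[: uniq.size].mean()
        return np.concatenate([[intercept], coef[uniq.size:]])
    raise ValueError(f"loss must be 'rmse' or 'mae', got {loss!r}")


def fit_segreg(
    subjects: list[Subject],
    loss: str = "mae",
    use_lesion: bool = False,
    min_pixels: int = _MIN_LABEL_PIXELS,
) -> SegRegressionModel:
    """Fit per-label response regressions over the pooled training pixels."""
    nbh = build_neighborhood(20)
    rows_X, rows_y, rows_g, rows_lab = [], [], [], []
    for k, s in enumerate(subjects):
        feats = pixel_features(s.image, nbh)
        names = _effective_label_names(s, use_lesion)
        sel = s.image.mask & (names != BG)
        rows_X.append(feats[sel])
        rows_y.append(np.asarray(s.response, dtype=float)[sel])
        rows_g.append(np.full(sel.sum(), k))
        rows_lab.append(names[sel])
    X = np.concatenate(rows_X)
    y = np.concatenate(rows_y)
    g = np.concatenate(rows_g)
    lab = np.concatenate(rows_lab)

    coefs: dict[str, np.ndarray] = {}
    pooled = None
    for name in pd.unique(lab):
        sel = lab == name
        if sel.sum() < min_pixels:
            warnings.warn(
                f"label {name} has {sel.sum()} training pixels "
                f"(< {min_pixels}); using pooled fallback",
                stacklevel=2,
            )
            if pooled is None:
                pooled = _fit_rows(X, y, g, loss)
            coefs[name] = pooled
        else:
            coefs[name] = _fit_rows(X[sel], y[sel], g[sel], loss)
    return SegRegressionModel(coefs, loss, use_lesion, nbh)


def predict_segreg(
    model: SegRegressionModel,
    image: ImageGrid,
    labels: LabelField,
    lesion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-pixel response prediction; NaN on BG (excluded) pixels."""
    subject = Subject("pred", image, labels, np.zeros(image.shape), lesion_mask)
    names = _effective_label_names(subject, model.use_lesion)
    feats = pixel_features(image, model.neighborhood)
    out = np.full(image.shape, np.nan)
    sel = image.mask & (names != BG)
    for name in np.unique(names[sel]):
        if name not in model.coefs:
            raise ValueError(f"label {name!r} was not present in training")
        c = model.coefs[name]
        rows = sel & (names == name)
        out[rows] = c[0] + feats[rows] @ c[1:]
    return out


# ---------------------------------------------------------------------------
# identity-basis additive model
# ---------------------------------------------------------------------------

@dataclass
class AdditiveModel:
    variant: str
    loss: str
    coef: np.ndarray
    columns: tuple[str, ...]

    def predict(self, design: np.ndarray) -> np.ndarray:
        return design @ self.coef


def additive_design(
    intensity: np.ndarray,
    neighbor_sums: np.ndarray | None = None,
    lesion: np.ndarray | None = None,
    variant: str = "markov",
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix of the identity-basis additive model.

    markov-: intercept + x. markov: + the 10 neighbour-pair sums.
    markov+: x split into lesion / non-lesion terms plus the lesion
    dummy interaction, neighbour terms on non-lesion pixels.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    x = np.asarray(intensity, dtype=float).ravel()
    cols = [np.ones_like(x)]
    names = ["const"]
    if variant == "markov+":
        if lesion is None:
            raise ValueError("markov+ requires a lesion dummy")
        li = np.asarray(lesion, dtype=float).ravel()
        cols += [x * (1 - li), x * li]
        names += ["x_nonlesion", "x_lesion"]
    else:
        cols.append(x)
        names.append("x")
    if variant in ("markov", "markov+"):
        if neighbor_sums is None:
            raise ValueError(f"{variant} requires neighbour sums")
        S = np.asarray(neighbor_sums, dtype=float).reshape(x.size, -1)
        if variant == "markov+":
            S = S * (1 - np.asarray(lesion, dtype=float).ravel()[:, None])
        cols += [S[:, k] for k in range(S.shape[1])]
        names += [f"s{k}" for k in range(S.shape[1])]
    return np.column_stack(cols), tuple(names)


def fit_additive(
    intensity: np.ndarray,
    response: np.ndarray,
    neighbor_sums: np.ndarray | None = None,
    lesion: np.ndarray | None = None,
    variant: str = "markov",
    loss: str = "rmse",
    basis: str = "identity",
) -> AdditiveModel:
    """Fit the linear (identity-basis) additive model.

    Only the identity basis is supported; spline bases are an external
    black box outside this package's scope.
    """
    if basis != "identity":
        raise NotImplementedError(
            "only the identity basis is implemented; spline GAMs are out of scope"
        )
    X, names = additive_design(intensity, neighbor_sums, lesion, variant)
    y = np.asarray(response, dtype=float).ravel()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    if loss == "rmse":
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    elif loss == "mae":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coef = np.asarray(sm.QuantReg(y, X).fit(q=0.5, max_iter=2000).params)
    else:
        raise ValueError(f"loss must be 'rmse' or 'mae', got {loss!r}")
    return AdditiveModel(variant, loss, coef, names)


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = np.sum((y - pred) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


def _pearson(y: np.ndarray, pred: np.ndarray) -> float:
    return float(np.corrcoef(y, pred)[0, 1])


def _residual_correlation(y: np.ndarray, pred: np.ndarray) -> float:
    """Pearson correlation between residuals and the true response —
    near zero for a model capturing all response structure."""
    resid = y - pred
    if np.allclose(resid.std(), 0.0):
        return 0.0
    return float(np.corrcoef(resid, y)[0, 1])


DEFAULT_METRICS = {
    "r2": _r2,
    "pearson_r": _pearson,
    "residual_correlation": _residual_correlation,
}


def loocv(
    subjects: list[Subject],
    fit_fn,
    predict_fn,
    metric_fns: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-subject-out cross-validation.

    ``fit_fn(train_subjects)`` returns a model; ``predict_fn(model,
    subject)`` returns ``(pred, truth)`` aligned 1D arrays for the
    held-out subject. Returns (per-subject metrics, mean±sd summary).
    """
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for LOOCV")
    metric_fns = metric_fns or DEFAULT_METRICS
    rows = {}
    for k, held_out in enumerate(subjects):
        train = subjects[:k] + subjects[k + 1:]
        model = fit_fn(train)
        pred, truth = predict_fn(model, held_out)
        keep = np.isfinite(pred) & np.isfinite(truth)
        rows[held_out.subject_id] = {
            name: fn(truth[keep], pred[keep]) for name, fn in metric_fns.items()
        }
    per_subject = pd.DataFrame(rows).T
    summary = per_subject.agg(["mean", "std"])
    return per_subject, summary
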