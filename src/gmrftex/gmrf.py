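"""Gaussian Markov random field segmentation with annealed Gibbs sampling.

Model
-----
Each tissue label ``l`` carries a mean ``mu_l``, a conditional variance
``beta00_l`` and 10 symmetric neighbour weights ``beta_l`` (one per
±offset pair of the 20-neighbour system). Conditionally on its
neighbours, a pixel's intensity is Gaussian:

    x_i | x_N(i) ~ N( mu_i + sum_j beta_{l,j} (x_j - mu_j),  beta00_l )

where ``mu_j`` is the mean of the neighbour's current label, and
neighbours that are background or off-lattice drop out of the sum. In
precision-matrix form this is Q_ii = 1/beta00_l and Q_ij = -beta_lj /
beta00_l; the conditional above is exactly the conditional of that joint
Gaussian on a single-label region.

The hidden label field is estimated by Gibbs sampling with simulated
annealing: labels are proposed from [density * gamma_l]^(1/t), with the
temperature schedule t(n) = ln4/ln(3+n) decaying to 0.25 at n = 253 and
zero (iterated conditional modes) for the final five iterations. Pixels
are updated in 3x3-block coding sets — no two pixels congruent mod (3,3)
are neighbours under the 20-neighbourhood — alternating with
pseudo-likelihood least-squares parameter re-estimation each sweep.

The background label is fixed at mu = 0, beta00 = 1e-30, beta = 0: after
masking, outside pixels are exactly 0 and the near-delta density pins
them to BG while making BG essentially impossible for tissue pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BG, LABELS, ImageGrid, LabelField, NeighborhoodSystem, build_neighborhood, shift

#: Prior tissue proportions for [CB, GM, PV, WM, BG], estimated from the
#: near-lesion-free day 28 cohort.
DEFAULT_GAMMA = np.array([0.010, 0.045, 0.030, 0.061, 0.854])

#: Fixed background parameters (mean, conditional variance).
BG_MU = 0.0
BG_BETA00 = 1e-30

#: Total annealing iterations: t(n) > 0 for n <= 253, t = 0 for 254..258.
N_ITERATIONS = 258

_MIN_LABEL_PIXELS = 50
_VAR_FLOOR = 1e-12


@dataclass
class TissueParams:
    """Per-label GMRF parameters: mean, conditional variance, pair weights."""

    mu: float
    beta00: float
    beta: np.ndarray  # (n_slots,)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        if self.beta00 <= 0:
            raise ValueError(f"beta00 must be positive, got {self.beta00}")


@dataclass
class GMRFModel:
    """Per-label parameters, prior proportions and the neighbourhood."""

    params: dict[str, TissueParams]
    gamma: np.ndarray
    neighborhood: NeighborhoodSystem
    label_set: tuple[str, ...] = field(default=LABELS)

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.label_set = tuple(self.label_set)
        if self.gamma.shape != (len(self.label_set),):
            raise ValueError("gamma must have one entry per label")
        if not np.isclose(self.gamma.sum(), 1.0):
            raise ValueError(f"gamma must sum to 1, got {self.gamma.sum()}")
        missing = set(self.label_set) - set(self.params)
        if missing:
            raise ValueError(f"missing parameters for labels: {sorted(missing)}")

    @property
    def n_slots(self) -> int:
        return self.neighborhood.n_slots

    def mu_array(self) -> np.ndarray:
        return np.array([self.params[l].mu for l in self.label_set])

    def beta00_array(self) -> np.ndarray:
        return np.array([self.params[l].beta00 for l in self.label_set])

    def beta_matrix(self) -> np.ndarray:
        return np.stack([self.params[l].beta for l in self.label_set])


def bg_params(n_slots: int = 10) -> TissueParams:
    return TissueParams(mu=BG_MU, beta00=BG_BETA00, beta=np.zeros(n_slots))


def default_model(
    params: dict[str, TissueParams],
    gamma: np.ndarray | None = None,
    neighborhood: NeighborhoodSystem | None = None,
    label_set: tuple[str, ...] = LABELS,
) -> GMRFModel:
    """Assemble a GMRFModel, filling in BG and the default prior."""
    neighborhood = neighborhood or build_neighborhood(20)
    params = dict(params)
    params.setdefault(BG, bg_params(neighborhood.n_slots))
    if gamma is None:
        if label_set == LABELS:
            gamma = DEFAULT_GAMMA.copy()
        else:
            gamma = np.full(len(label_set), 1.0 / len(label_set))
    return GMRFModel(params, gamma, neighborhood, label_set)


# ---------------------------------------------------------------------------
# annealing schedule
# ---------------------------------------------------------------------------

def temperature(n: int) -> float:
    """Annealing temperature at iteration ``n`` (1-based).

    t(n) = ln(4)/ln(3+n) for n <= 253 (so t(1) = 1 and t(253) = 0.25),
    and t = 0 for the final iterations 254..258 (ICM).
    """
    if not 1 <= n <= N_ITERATIONS:
        raise ValueError(f"iteration must be in [1, {N_ITERATIONS}], got {n}")
    if n <= 253:
        return float(np.log(4.0) / np.log(3.0 + n))
    return 0.0


# ---------------------------------------------------------------------------
# conditional density
# ---------------------------------------------------------------------------

def _pair_sums(
    values: np.ndarray,
    mu_map: np.ndarray,
    valid: np.ndarray,
    nbh: NeighborhoodSystem,
) -> np.ndarray:
    """Per-slot sums of neighbour deviations, (n_slots, H, W).

    S_k[i] = sum over the slot's ± offsets of (x_j - mu_j) for valid
    (in-mask, non-BG, on-lattice) neighbours j of pixel i.
    """
    dev = np.where(valid, values - mu_map, 0.0)
    sums = np.zeros((nbh.n_slots,) + values.shape)
    for (dy, dx), slot in zip(nbh.offsets, nbh.pair_slot):
        sums[slot] += shift(dev, dy, dx)
    return sums


def _label_logdensity(
    values: np.ndarray, pair_sums: np.ndarray, model: GMRFModel
) -> np.ndarray:
    """Log conditional density of every pixel under every label, (L, H, W)."""
    mu = model.mu_array()
    beta00 = model.beta00_array()
    beta = model.beta_matrix()  # (L, n_slots)
    m = mu[:, None, None] + np.tensordot(beta, pair_sums, axes=(1, 0))
    resid2 = (values[None] - m) ** 2
    with np.errstate(over="ignore"):
        out = -0.5 * np.log(2.0 * np.pi * beta00)[:, None, None] - resid2 / (
            2.0 * beta00[:, None, None]
        )
    return out


def conditional_density(
    x_i: float,
    neighbor_values: np.ndarray,
    neighbor_mus: np.ndarray,
    label: str,
    model: GMRFModel,
    log: bool = False,
) -> float:
    """Conditional Gaussian density of one pixel under one tissue label.

    ``neighbor_values`` and ``neighbor_mus`` are aligned with the
    neighbourhood's offset order; NaN entries mark missing neighbours
    (off-lattice or background) and drop out of the sum.
    """
    if label == BG:
        raise ValueError("conditional density is undefined for the BG label")
    p = model.params[label]
    if p.beta00 <= 0:
        raise ValueError("beta00 must be positive")
    nv = np.asarray(neighbor_values, dtype=float)
    nm = np.asarray(neighbor_mus, dtype=float)
    dev = np.where(np.isfinite(nv) & np.isfinite(nm), nv - nm, 0.0)
    slots = np.asarray(model.neighborhood.pair_slot)
    sums = np.bincount(slots, weights=dev, minlength=model.n_slots)
    m = p.mu + float(p.beta @ sums)
    logd = -0.5 * np.log(2.0 * np.pi * p.beta00) - (x_i - m) ** 2 / (2.0 * p.beta00)
    return float(logd) if log else float(np.exp(logd))


# ---------------------------------------------------------------------------
# Gibbs sampling
# ---------------------------------------------------------------------------

def _field_logdensity(
    labels: LabelField, image: ImageGrid, model: GMRFModel
) -> np.ndarray:
    mu = model.mu_array()
    mu_map = mu[labels.labels]
    valid = image.mask & (labels.labels != labels.bg_index)
    sums = _pair_sums(image.values, mu_map, valid, model.neighborhood)
    return _label_logdensity(image.values, sums, model)


def proposal_probabilities(
    i: tuple[int, int],
    labels: LabelField,
    image: ImageGrid,
    model: GMRFModel,
    t: float,
) -> np.ndarray:
    """Annealed label-proposal probabilities for one pixel.

    For t > 0, p(l) ∝ [p(x_i | neighbours, l) * gamma_l]^(1/t); for
    t = 0 a one-hot vector at the argmax (ICM), ties toward the lower
    label index.
    """
    if t < 0:
        raise ValueError("temperature must be nonnegative")
    if not np.isfinite(image.values[i]):
        raise FloatingPointError(f"non-finite intensity at pixel {i}")
    logd = _field_logdensity(labels, image, model)[:, i[0], i[1]]
    logp = logd + np.log(model.gamma)
    if t == 0.0:
        out = np.zeros_like(logp)
        out[np.argmax(logp)] = 1.0
        return out
    logp = logp / t
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


_CODING_SETS = 9  # 3x3 block colouring: valid for all offsets |dy|,|dx| <= 2


def _coding_masks(shape: tuple[int, int]) -> list[np.ndarray]:
    yy, xx = np.indices(shape)
    code = (yy % 3) * 3 + (xx % 3)
    return [code == s for s in range(_CODING_SETS)]


def gibbs_sweep(
    labels: LabelField,
    image: ImageGrid,
    model: GMRFModel,
    t: float,
    rng: np.random.Generator | int,
) -> LabelField:
    """One full annealed Gibbs sweep over the nine 3x3 coding sets.

    Pixels in a coding set are mutually non-neighbouring and update
    simultaneously; BG pixels outside the mask are frozen. Deterministic
    given the generator state / seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = labels.copy()
    log_gamma = np.log(model.gamma)
    for set_mask in _coding_masks(out.shape):
        update = set_mask & image.mask
        if not update.any():
            continue
        logd = _field_logdensity(out, image, model)
        logp = logd[:, update] + log_gamma[:, None]
        if t == 0.0:
            choice = np.argmax(logp, axis=0)
        else:
            g = rng.gumbel(size=logp.shape)
            choice = np.argmax(logp / t + g, axis=0)
        out.labels[update] = choice
    return out


# ---------------------------------------------------------------------------
# pseudo-likelihood parameter estimation
# ---------------------------------------------------------------------------

def estimate_params(
    labels: LabelField,
    image: ImageGrid,
    neighborhood: NeighborhoodSystem | None = None,
    min_pixels: int = _MIN_LABEL_PIXELS,
) -> dict[str, TissueParams]:
    """Least-squares GMRF parameter estimates per label.

    For each non-BG label: the mean is the in-label intensity average;
    the pair weights regress the centered pixel value on the 10
    symmetric-pair neighbour-deviation sums over in-label pixels; beta00
    is the residual variance. Labels below ``min_pixels`` fall back to
    beta = 0 with beta00 the in-label variance (with a warning); BG is
    fixed. Labels with no pixels are omitted from the result.
    """
    nbh = neighborhood or build_neighborhood(20)
    bg_idx = labels.bg_index
    x = image.values
    n_labels = len(labels.label_set)

    mu_hat = np.zeros(n_labels)
    counts = np.zeros(n_labels, dtype=int)
    for li, name in enumerate(labels.label_set):
        if name == BG:
            continue
        sel = (labels.labels == li) & image.mask
        counts[li] = sel.sum()
        if counts[li]:
            mu_hat[li] = x[sel].mean()

    mu_map = mu_hat[labels.labels]
    valid = image.mask & (labels.labels != bg_idx)
    sums = _pair_sums(x, mu_map, valid, nbh)

    out: dict[str, TissueParams] = {BG: bg_params(nbh.n_slots)}
    for li, name in enumerate(labels.label_set):
        if name == BG or counts[li] == 0:
            continue
        sel = (labels.labels == li) & image.mask
        y = x[sel] - mu_hat[li]
        if counts[li] < min_pixels:
            warnings.warn(
                f"label {name} has only {counts[li]} pixels "
                f"(< {min_pixels}); falling back to iid estimate",
                stacklevel=2,
            )
            beta00 = max(float(np.var(y)), _VAR_FLOOR)
            out[name] = TissueParams(mu_hat[li], beta00, np.zeros(nbh.n_slots))
            continue
        X = sums[:, sel].T  # (n, n_slots)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        beta00 = max(float(np.mean(resid**2)), _VAR_FLOOR)
        out[name] = TissueParams(float(mu_hat[li]), beta00, beta)
    return out


# ---------------------------------------------------------------------------
# full segmentation
# ---------------------------------------------------------------------------

def segment(
    image: ImageGrid,
    init: LabelField,
    model0: GMRFModel | None = None,
    seed: int = 0,
) -> tuple[LabelField, GMRFModel]:
    """Annealed GMRF segmentation from a (GMM) initialization.

    Alternates one Gibbs sweep at temperature t(n) with pseudo-likelihood
    parameter re-estimation for n = 1..258; the final five iterations run
    at t = 0 (ICM). Returns the final hard labels and fitted model.
    """
    if BG not in init.label_set:
        raise ValueError("initialization must include the BG label")
    if model0 is None:
        params = estimate_params(init, image)
        model0 = default_model(params, label_set=init.label_set)
        for name in init.label_set:
            if name not in params:
                model0.params[name] = TissueParams(
                    0.5, 0.01, np.zeros(model0.n_slots)
                )
    if model0.label_set != init.label_set:
        raise ValueError("model and init label sets differ")

    labels = init.copy()
    model = replace(model0, params=dict(model0.params))
    streams = np.random.SeedSequence(seed).spawn(N_ITERATIONS)
    for n in range(1, N_ITERATIONS + 1):
        t = temperature(n)
        rng = np.random.default_rng(streams[n - 1])
        labels = gibbs_sweep(labels, image, model, t, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = estimate_params(labels, image, model.neighborhood)
        for name, p in est.items():
            if name != BG:
                model.params[name] = p
    return labels, model


def drop_label_renormalize(
    labels: LabelField, image: ImageGrid, model: GMRFModel, obsolete: str
) -> tuple[LabelField, GMRFModel]:
    """Remove an obsolete label (e.g. PV) and renormalize the prior.

    Pixels carrying the obsolete label are reassigned to the argmax of
    the annealed proposal over the remaining labels at t = 0, evaluated
    simultaneously in the pre-drop neighbour context.
    """
    if obsolete not in labels.label_set:
        raise ValueError(f"label {obsolete!r} not in label set")
    remaining = tuple(n for n in labels.label_set if n != obsolete)
    if len([n for n in remaining if n != BG]) < 3:
        raise ValueError(
            "dropping this label would leave fewer than 3 tissue groups; "
            "multilateration requires at least 3"
        )
    gamma = np.array(
        [model.gamma[model.label_set.index(n)] for n in remaining]
    )
    gamma = gamma / gamma.sum()
    new_model = GMRFModel(
        {n: model.params[n] for n in remaining},
        gamma,
        model.neighborhood,
        remaining,
    )

    old_idx = {n: labels.label_set.index(n) for n in labels.label_set}
    new_labels = np.empty_like(labels.labels)
    for ni, name in enumerate(remaining):
        new_labels[labels.labels == old_idx[name]] = ni

    drop_sel = labels.labels == old_idx[obsolete]
    if drop_sel.any():
        logd = _field_logdensity(labels, image, model)
        keep_rows = [old_idx[n] for n in remaining]
        logp = logd[keep_rows][:, drop_sel] + np.log(gamma)[:, None]
        new_labels[drop_sel] = np.argmax(logp, axis=0)
    return LabelField(new_labels, remaining), new_model
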