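"""Seeded synthetic spinal-cord phantom with full ground truth.

Generates a pre-aligned MRI-like / histology-like image pair on a small
lattice so that every pipeline stage is testable without any download:
an elliptical cord (BG outside), an H-shaped grey-matter region, white
matter surround, small cell-body blobs standing in for the substantia
gelatinosa, an optional partial-volume ring at the WM/GM interface, and
an optional ventral-WM lesion disc (pooled into CB, as lesions are).

The MRI channel is drawn from the GMRF texture model itself (per-tissue
mean, conditional variance and neighbour weights), so simulate → estimate
round trips are exact by construction. Histology channels are per-tissue
Gaussian noise around the configured staining means; the defaults are the
published per-tissue blue/red means (WM 0.735/0.230, GM 0.333/0.666,
CB 0.341/0.785). Geometry is parametric, not an anatomical atlas: only
the statistical structure matters for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import LABELS, ImageGrid, LabelField, build_neighborhood
from .gmrf import GMRFModel, TissueParams, bg_params, default_model
from .simulate import simulate_field

#: Contrast presets: within-tissue conditional standard deviation of MRI.
CONTRAST_SD = {"high": 0.03, "medium": 0.06, "low": 0.10}

_MRI_MEANS = {"WM": 0.30, "PV": 0.45, "GM": 0.60, "CB": 0.82}
#: neighbour pair weights (slot 0 = horizontal pair, slot 1 = vertical)
_MRI_BETA = {
    "WM": {0: 0.10, 1: 0.05},
    "GM": {0: 0.08, 1: 0.04},
    "PV": {},
    "CB": {},
}
_HIST_MEANS = {
    #        blue (myelin), red (cellularity)
    "WM": (0.735, 0.230),
    "GM": (0.333, 0.666),
    "CB": (0.341, 0.785),
    "PV": (0.534, 0.448),  # WM/GM midpoint: mixed-voxel staining
    "BG": (0.050, 0.050),
}


@dataclass
class PhantomConfig:
    """Tunable phantom parameters; defaults give the high-contrast case."""

    contrast: str = "high"
    mri_means: dict[str, float] = field(default_factory=lambda: dict(_MRI_MEANS))
    mri_sd: float | None = None  # overrides the contrast preset
    mri_beta: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _MRI_BETA.items()}
    )
    hist_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_HIST_MEANS)
    )
    hist_sd: float = 0.10
    hist_bg_sd: float = 0.02
    pv_ring: bool = True
    lesion: bool = False
    dark_core: bool = False  # lesion core darker than WM (known failure mode)
    lesion_mri_mean: float = 0.78  # bright like CB unless dark_core
    dark_core_mri_mean: float = 0.20
    n_sweeps: int = 200
    gamma: np.ndarray | None = None  # optional prior proportions to store
    # geometry, as fractions of the image extent
    cord_semiaxes: tuple[float, float] = (0.26, 0.30)  # (ry, rx)
    gm_arm_halfwidth: float = 0.045
    gm_arm_x: float = 0.13
    gm_arm_halfheight: float = 0.185
    gm_bar_halfheight: float = 0.05
    cb_radius: float = 0.055
    lesion_radius: float = 0.08

    def __post_init__(self) -> None:
        if self.contrast not in CONTRAST_SD:
            raise ValueError(f"contrast must be one of {sorted(CONTRAST_SD)}")
        if self.gamma is not None:
            g = np.asarray(self.gamma, dtype=float)
            if g.min() < 0 or not np.isclose(g.sum(), 1.0):
                raise ValueError("configured proportions must form a simplex")
            self.gamma = g

    @property
    def sd(self) -> float:
        return self.mri_sd if self.mri_sd is not None else CONTRAST_SD[self.contrast]


@dataclass
class PhantomTruth:
    """Ground truth bundle: labels, images, generating model, seed."""

    labels: LabelField
    mri: ImageGrid
    hist_blue: ImageGrid
    hist_red: ImageGrid
    gen_params: GMRFModel
    config: PhantomConfig
    seed: int
    gamma: np.ndarray  # realized label proportions over the full frame
    lesion_mask: np.ndarray | None = None


def _geometry(size: tuple[int, int], cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray | None]:
    """Integer label map in LABELS order plus the optional lesion mask."""
    h, w = size
    yy, xx = np.indices(size)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    u = (yy - cy) / h  # fractional offsets from centre
    v = (xx - cx) / w

    idx = {name: LABELS.index(name) for name in LABELS}
    labels = np.full(size, idx["BG"], dtype=np.int64)
    ry, rx = cfg.cord_semiaxes
    cord = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
    labels[cord] = idx["WM"]

    arms = (np.abs(np.abs(v) - cfg.gm_arm_x) <= cfg.gm_arm_halfwidth) & (
        np.abs(u) <= cfg.gm_arm_halfheight
    )
    bar = (np.abs(u) <= cfg.gm_bar_halfheight) & (np.abs(v) <= cfg.gm_arm_x)
    gm = (arms | bar) & cord
    labels[gm] = idx["GM"]

    # substantia gelatinosa: blobs at the dorsal (top) horn tips
    for sx in (-1, 1):
        blob = (u + cfg.gm_arm_halfheight) ** 2 + (v - sx * cfg.gm_arm_x) ** 2 <= (
            cfg.cb_radius**2
        )
        labels[blob & cord] = idx["CB"]

    lesion_mask = None
    if cfg.lesion or cfg.dark_core:
        lesion_mask = ((u - 0.18) ** 2 + v**2 <= cfg.lesion_radius**2) & cord
        labels[lesion_mask] = idx["CB"]

    if cfg.pv_ring:
        wm = labels == idx["WM"]
        gm_now = labels == idx["GM"]
        near_gm = np.zeros(size, dtype=bool)
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            near_gm |= np.roll(np.roll(gm_now, dy, axis=0), dx, axis=1)
        labels[wm & near_gm] = idx["PV"]
    return labels, lesion_mask


def make_phantom(
    size: tuple[int, int] = (64, 64),
    config: PhantomConfig | None = None,
    seed: int = 0,
) -> PhantomTruth:
    """Generate the synthetic cord phantom; bit-deterministic given seed."""
    if size[0] < 32 or size[1] < 32:
        raise ValueError("phantom size must be at least 32x32")
    cfg = config or PhantomConfig()
    label_arr, lesion_mask = _geometry(size, cfg)
    truth = LabelField(label_arr, LABELS)

    nbh = build_neighborhood(20)
    var = cfg.sd**2
    params = {}
    for name in ("CB", "GM", "PV", "WM"):
        beta = np.zeros(nbh.n_slots)
        for slot, val in cfg.mri_beta.get(name, {}).items():
            beta[slot] = val
        params[name] = TissueParams(cfg.mri_means[name], var, beta)
    params["BG"] = bg_params(nbh.n_slots)

    counts = np.bincount(label_arr.ravel(), minlength=len(LABELS))
    realized_gamma = counts / counts.sum()
    gen = default_model(
        params, gamma=cfg.gamma if cfg.gamma is not None else realized_gamma,
        neighborhood=nbh,
    )

    ss = np.random.SeedSequence([seed, 20210405]).spawn(3)
    sim_labels = truth
    sim_model = gen
    if (cfg.lesion or cfg.dark_core) and lesion_mask is not None:
        # lesion core gets its own simulation label so its MRI mean can
        # differ from the SG blobs, while the truth label stays CB
        ext_set = LABELS + ("LC",)
        ext_arr = label_arr.copy()
        ext_arr[lesion_mask] = len(LABELS)
        ext_params = dict(params)
        ext_params["LC"] = TissueParams(
            cfg.dark_core_mri_mean if cfg.dark_core else cfg.lesion_mri_mean,
            var,
            np.zeros(nbh.n_slots),
        )
        ext_counts = np.bincount(ext_arr.ravel(), minlength=len(ext_set))
        sim_model = GMRFModel(
            ext_params, ext_counts / ext_counts.sum(), nbh, ext_set
        )
        sim_labels = LabelField(ext_arr, ext_set)

    mri = simulate_field(
        sim_labels, sim_model, n_sweeps=cfg.n_sweeps,
        seed=np.random.default_rng(ss[0]),
    )

    rng = np.random.default_rng(ss[1])
    blue = np.zeros(size)
    red = np.zeros(size)
    for li, name in enumerate(LABELS):
        sel = label_arr == li
        if not sel.any():
            continue
        mb, mr = cfg.hist_means[name]
        sd = cfg.hist_bg_sd if name == "BG" else cfg.hist_sd
        blue[sel] = mb + sd * rng.standard_normal(sel.sum())
        red[sel] = mr + sd * rng.standard_normal(sel.sum())
    blue = np.clip(blue, 0.0, 1.0)
    red = np.clip(red, 0.0, 1.0)
    mask = label_arr != LABELS.index("BG")

    return PhantomTruth(
        labels=truth,
        mri=mri,
        hist_blue=ImageGrid(blue, mask),
        hist_red=ImageGrid(red, mask),
        gen_params=gen,
        config=cfg,
        seed=seed,
        gamma=realized_gamma,
        lesion_mask=lesion_mask,
    )
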