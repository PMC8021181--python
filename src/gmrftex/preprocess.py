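"""Intensity normalization and resolution matching.

Histology RGB images are normalized in two steps — pixel-wise (each
channel divided by the pixel's summed RGB intensity) then channel-wise
min–max to [0, 1] — yielding a blue (myelin density) and a red
(cellularity density) grid. High-resolution histology is brought to the
MRI scale with a Gaussian pyramid (5-tap binomial kernel, blur then
decimate by 2 per level). MRI is min–max normalized over the mask
interior only, with masked-out pixels set to 0.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve1d

from .core import ImageGrid

# classic 5-tap binomial approximation to the Gaussian
_PYRAMID_KERNEL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _minmax_over_mask(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min–max rescale over masked-in pixels; degenerate range maps to 0."""
    out = np.zeros_like(values, dtype=float)
    inside = values[mask]
    lo, hi = inside.min(), inside.max()
    if hi > lo:
        out[mask] = (inside - lo) / (hi - lo)
    return out


def normalize_histology(
    rgb_image: np.ndarray, mask: np.ndarray | None = None
) -> tuple[ImageGrid, ImageGrid]:
    """Normalize an RGB histology image into blue and red density grids.

    Returns ``(blue, red)`` ImageGrids: blue tracks myelin staining,
    red tracks cellularity staining.
    """
    rgb = np.asarray(rgb_image, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got {rgb.shape}")
    if rgb.min() < 0:
        raise ValueError("channels must be non-negative")
    total = rgb.sum(axis=2)
    if not np.any(total > 0):
        raise ValueError("all-zero image: no pixel with positive intensity")
    if mask is None:
        mask = np.ones(total.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)

    # pixel-wise shares; zero-total pixels (background) get share 0
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(total[..., None] > 0, rgb / total[..., None], 0.0)
    blue = _minmax_over_mask(shares[..., 2], mask)
    red = _minmax_over_mask(shares[..., 0], mask)
    return ImageGrid(blue, mask), ImageGrid(red, mask)


def _reduce_once(values: np.ndarray) -> np.ndarray:
    blurred = convolve1d(values, _PYRAMID_KERNEL, axis=0, mode="reflect")
    blurred = convolve1d(blurred, _PYRAMID_KERNEL, axis=1, mode="reflect")
    return blurred[::2, ::2]


def pyramid_downsample(image: ImageGrid, target_shape: tuple[int, int]) -> ImageGrid:
    """Gaussian-pyramid downsample to ``target_shape``.

    Source dimensions must be the target dimensions times the same power
    of two; embed the image in a uniform background canvas first if not.
    """
    h, w = image.shape
    th, tw = target_shape
    if th <= 0 or tw <= 0 or h % th or w % tw:
        raise ValueError(
            f"cannot downsample {h}x{w} to {th}x{tw}: pad the image into a "
            "uniform background canvas with power-of-two ratio first"
        )
    ry, rx = h // th, w // tw
    if ry != rx or ry & (ry - 1):
        raise ValueError(
            f"size ratio must be the same power of two on both axes, got "
            f"{ry}x{rx}: pad the image first"
        )
    values = image.values.copy()
    mask = image.mask.astype(float)
    k = ry.bit_length() - 1
    for _ in range(k):
        values = _reduce_once(values)
        mask = _reduce_once(mask)
    return ImageGrid(values, mask > 0.5)


def normalize_mri(image: np.ndarray, mask: np.ndarray) -> ImageGrid:
    """Min–max normalize an MRI slice over the mask interior to [0, 1]."""
    values = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    inside = values[mask]
    if inside.max() == inside.min():
        raise ValueError("masked region is constant: no contrast to normalize")
    return ImageGrid(_minmax_over_mask(values, mask), mask)
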