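"""Lattice data model shared by every stage.

The pipeline works on 2D grayscale images with a binary tissue mask,
a categorical hidden-label field over the tissue classes, and a symmetric
neighbourhood system on the square lattice. Coordinates are 0-based
row-major; an offset ``(dy, dx)`` has ``y`` increasing downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical tissue label order. CB = cell body (substantia gelatinosa +
#: lesion), GM = grey matter, PV = partial volume, WM = white matter,
#: BG = background. Index order fixes argmax tie-breaking.
LABELS = ("CB", "GM", "PV", "WM", "BG")
BG = "BG"

#: Admissible symmetric neighbour counts: complete shells of the square
#: lattice at squared radii {1}, {1,2}, {1,2,4}, {1,2,4,5}.
_ADMISSIBLE_N = (4, 8, 12, 20)


@dataclass(frozen=True)
class ImageGrid:
    """A 2D intensity lattice in [0, 1] with a binary tissue mask."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if values.ndim != 2:
            raise ValueError(f"values must be 2D, got shape {values.shape}")
        if mask.shape != values.shape:
            raise ValueError(
                f"mask shape {mask.shape} != values shape {values.shape}"
            )
        if not np.all(np.isfinite(values[mask])):
            raise ValueError("masked-in values must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class NeighborhoodSystem:
    """Symmetric lattice neighbourhood with shared parameters per ±pair.

    ``offsets`` is the ordered list of ``(dy, dx)`` displacements, sorted
    by radial distance then angle from the +x axis; ``pair_slot[k]`` maps
    offset ``k`` to one of ``n_slots`` symmetric parameter slots, with
    ``o`` and ``-o`` sharing a slot.
    """

    offsets: tuple[tuple[int, int], ...]
    pair_slot: tuple[int, ...]

    @property
    def n_slots(self) -> int:
        return len(self.offsets) // 2

    def slot_offsets(self, slot: int) -> list[tuple[int, int]]:
        """The (two) offsets sharing a parameter slot."""
        return [o for o, s in zip(self.offsets, self.pair_slot) if s == slot]


def build_neighborhood(n_neighbors: int = 20) -> NeighborhoodSystem:
    """Build the symmetric n-nearest-neighbour system on the square lattice.

    The 20-neighbour system (squared radii 1, 2, 4, 5) has 10 unique
    symmetric parameter slots and is the default used throughout.

    Parameters
    ----------
    n_neighbors : int
        One of 4, 8, 12, 20 — the symmetric shells of the lattice.
    """
    if n_neighbors not in _ADMISSIBLE_N:
        raise ValueError(
            f"n_neighbors must be one of {_ADMISSIBLE_N}, got {n_neighbors}"
        )
    candidates = []
    for dy in range(-2, 3):
        for dx in range(-2, 3):
            r2 = dy * dy + dx * dx
            if 1 <= r2 <= 5:
                # angle measured counter-clockwise from +x with y downward
                angle = math.atan2(-dy, dx) % (2.0 * math.pi)
                candidates.append((r2, angle, (dy, dx)))
    candidates.sort()
    offsets = tuple(o for _, _, o in candidates[:n_neighbors])

    slot_of: dict[tuple[int, int], int] = {}
    pair_slot = []
    next_slot = 0
    for dy, dx in offsets:
        if (dy, dx) in slot_of:
            pair_slot.append(slot_of[(dy, dx)])
        else:
            slot_of[(dy, dx)] = next_slot
            slot_of[(-dy, -dx)] = next_slot
            pair_slot.append(next_slot)
            next_slot += 1
    return NeighborhoodSystem(offsets=offsets, pair_slot=tuple(pair_slot))


@dataclass
class LabelField:
    """Per-pixel hard tissue assignment over an ordered label set."""

    labels: np.ndarray  # integer indices into label_set
    label_set: tuple[str, ...] = field(default=LABELS)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2D array of indices")
        if labels.min(initial=0) < 0 or labels.max(initial=0) >= len(self.label_set):
            raise ValueError("label index outside label_set")
        self.labels = labels.astype(np.int64)
        self.label_set = tuple(self.label_set)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def index(self, name: str) -> int:
        return self.label_set.index(name)

    @property
    def bg_index(self) -> int:
        return self.label_set.index(BG)

    def of(self, name: str) -> np.ndarray:
        """Boolean map of pixels carrying the named label."""
        return self.labels == self.index(name)

    def copy(self) -> "LabelField":
        return LabelField(self.labels.copy(), self.label_set)


def shift(array: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    """Shift so that ``out[i, j] = array[i + dy, j + dx]``, zero-padded.

    ``out[i, j]`` holds the value of the neighbour at offset ``(dy, dx)``
    from pixel ``(i, j)``; off-lattice positions read ``fill``.
    """
    h, w = array.shape
    out = np.full_like(array, fill)
    ys = slice(max(0, -dy), min(h, h - dy))
    xs = slice(max(0, -dx), min(w, w - dx))
    ysrc = slice(max(0, dy), min(h, h + dy))
    xsrc = slice(max(0, dx), min(w, w + dx))
    out[ys, xs] = array[ysrc, xsrc]
    return out
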