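"""File round-trips: images, masks, label maps and model JSON.

Grayscale/RGB images are read from PNG/TIFF (8/16-bit, rescaled to
[0, 1]) or single-slice NIfTI; label maps are written as indexed PNG
with a JSON sidecar carrying the index→name mapping, the fitted model
and the seed; feature maps go to 2-channel float TIFF or NIfTI with a
JSON provenance record.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .core import ImageGrid, LabelField, NeighborhoodSystem, build_neighborhood
from .gmrf import GMRFModel, TissueParams
from .metric import FeatureMap


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale or RGB image as float in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    if _is_nifti(path):
        data = np.asanyarray(nib.load(path).dataobj, dtype=float)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"expected a single 2D slice in {path}")
        return data
    raw = np.asarray(iio.imread(path))
    arr = raw.astype(float)
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    return arr


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask: nonzero = inside."""
    return read_image(path) > 0


def write_image(path: str | Path, values: np.ndarray) -> None:
    path = Path(path)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), np.eye(4)), path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    else:
        arr = np.clip(np.asarray(values, dtype=float), 0.0, 1.0)
        iio.imwrite(path, (arr * 65535).astype(np.uint16))


def _params_to_json(p: TissueParams) -> dict:
    return {"mu": p.mu, "beta00": p.beta00, "beta": list(map(float, p.beta))}


def model_to_json(model: GMRFModel, seed: int | None = None) -> dict:
    return {
        "label_set": list(model.label_set),
        "gamma": list(map(float, model.gamma)),
        "n_neighbors": len(model.neighborhood.offsets),
        "params": {n: _params_to_json(p) for n, p in model.params.items()},
        "seed": seed,
    }


def model_from_json(doc: dict) -> GMRFModel:
    nbh = build_neighborhood(doc["n_neighbors"])
    params = {
        n: TissueParams(p["mu"], p["beta00"], np.asarray(p["beta"]))
        for n, p in doc["params"].items()
    }
    return GMRFModel(params, np.asarray(doc["gamma"]), nbh, tuple(doc["label_set"]))


def write_labels(
    path: str | Path,
    labels: LabelField,
    model: GMRFModel | None = None,
    seed: int | None = None,
) -> None:
    """Write an indexed-PNG label map plus a JSON sidecar."""
    path = Path(path)
    iio.imwrite(path, labels.labels.astype(np.uint8))
    sidecar = {"label_set": list(labels.label_set)}
    if model is not None:
        sidecar["model"] = model_to_json(model, seed)
    elif seed is not None:
        sidecar["seed"] = seed
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_labels(path: str | Path) -> tuple[LabelField, GMRFModel | None]:
    path = Path(path)
    arr = np.asarray(iio.imread(path)).astype(np.int64)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    field = LabelField(arr, tuple(sidecar["label_set"]))
    model = model_from_json(sidecar["model"]) if "model" in sidecar else None
    return field, model


def write_feature_maps(path: str | Path, fmap: FeatureMap, seed: int | None = None) -> None:
    """Write (myelin, cellularity) as a 2-channel float TIFF or NIfTI
    plus a JSON provenance sidecar (landmarks, scales, seed)."""
    path = Path(path)
    stack = np.stack([fmap.myelin, fmap.cellularity]).astype(np.float32)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(np.moveaxis(stack, 0, -1), np.eye(4)), path)
    else:
        tifffile.imwrite(path, stack)
    prov = {
        "channels": ["myelin", "cellularity"],
        "scales": list(map(float, fmap.space.scales)),
        "mri_landmarks": {k: list(map(float, v)) for k, v in fmap.space.mri_landmarks.items()},
        "hist_landmarks": {k: list(map(float, v)) for k, v in fmap.space.hist_landmarks.items()},
        "seed": seed,
    }
    path.with_suffix(".json").write_text(json.dumps(prov, indent=1))
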