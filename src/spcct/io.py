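"""File output helpers: NIfTI/TIFF images, CSV tables, JSON/YAML configs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml

__all__ = [
    "save_nifti",
    "save_tiff",
    "write_json",
    "read_config",
    "write_config",
    "config_hash",
]


def save_nifti(image: np.ndarray, voxel_size_um: float, path) -> Path:
    """Write an image (or stack) as NIfTI with the voxel size in the header."""
    path = Path(path)
    arr = np.asarray(image, dtype=np.float32)
    affine = np.diag([voxel_size_um * 1e-3] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.atleast_3d(arr), affine), str(path))
    return path


def save_tiff(image: np.ndarray, path, voxel_size_um: float | None = None) -> Path:
    """Write an image or stack as 32-bit TIFF with resolution metadata."""
    path = Path(path)
    arr = np.asarray(image, dtype=np.float32)
    kwargs = {}
    if voxel_size_um:
        per_cm = 10000.0 / voxel_size_um
        kwargs = {"resolution": (per_cm, per_cm), "resolutionunit": "CENTIMETER"}
    tifffile.imwrite(str(path), arr, **kwargs)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")
    return path


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def read_config(path) -> dict:
    """Read an experiment config from YAML or JSON (same schema)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_config(cfg: dict, path) -> Path:
    path = Path(path)
    if path.suffix.lower() == ".json":
        return write_json(cfg, path)
    path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return path


def config_hash(cfg: dict) -> str:
    """Stable content hash of a config dict."""
    blob = json.dumps(cfg, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
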