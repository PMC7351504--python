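"""NIfTI / TSV / JSON persistence helpers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "save_volume", "load_volume", "save_maps_4d", "load_maps_4d",
    "save_table", "load_table", "save_json", "load_json",
]


def _affine(voxel_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_mm
    return aff


def save_volume(path, vol: np.ndarray, voxel_mm: float = 3.0) -> None:
    """Write a 3D map (or boolean mask) as a NIfTI-1 volume."""
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), _affine(voxel_mm))
    img.to_filename(str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_maps_4d(path, maps: np.ndarray, mask: np.ndarray,
                 voxel_mm: float = 3.0) -> None:
    """Write k component maps (k × V over mask voxels) as one 4D NIfTI."""
    from .preprocess import unmask

    vols = unmask(maps, mask)  # k × grid
    img = nib.Nifti1Image(
        np.moveaxis(vols, 0, -1).astype(np.float32), _affine(voxel_mm)
    )
    img.to_filename(str(path))


def load_maps_4d(path, mask: np.ndarray) -> np.ndarray:
    from .preprocess import apply_mask

    data = np.asarray(nib.load(str(path)).get_fdata())
    vols = np.moveaxis(data, -1, 0)
    return apply_mask(vols, mask)


def save_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def load_json(path):
    return json.loads(Path(path).read_text())
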