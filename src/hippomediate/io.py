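"""File formats at the pipeline boundary.

NIfTI for images and masks (spatial axes first on disk, time-first in
memory), whitespace-delimited 6-column text for motion traces, TSV for
behavioral tables, QC reports and cluster tables, YAML for configuration,
JSON for provenance. Readers validate structure and report the offending
row or file on malformed input.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .types import BEHAVIOR_COLUMNS, MotionParams, Volume4D, validate_behavior

__all__ = [
    "save_volume",
    "load_volume",
    "save_labels",
    "load_labels",
    "save_map",
    "load_map",
    "save_motion",
    "load_motion",
    "save_behavior",
    "load_behavior",
    "save_yaml",
    "load_yaml",
    "save_json",
]


def save_volume(vol: Volume4D, path: str | Path) -> Path:
    """Write a 4D image; time becomes the last axis, TR goes into the header."""
    path = Path(path)
    data = np.moveaxis(vol.data, 0, -1)
    img = nib.Nifti1Image(data.astype(np.float32), vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size) + (vol.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> Volume4D:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Volume4D(
        data=np.moveaxis(data, -1, 0),
        voxel_size=tuple(float(z) for z in zooms[:3]),
        tr=tr,
        affine=np.asarray(img.affine),
    )


def save_labels(labels: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    aff = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), aff), str(path))
    return path


def load_labels(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj).astype(int)


def save_map(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> Path:
    """Write a 3D statistical map."""
    path = Path(path)
    aff = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), aff), str(path))
    return path


def load_map(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got shape {data.shape}")
    return data


def save_motion(motion: MotionParams, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, motion.values, fmt="%.8f")
    return path


def load_motion(path: str | Path) -> MotionParams:
    """Read a 6-column motion file; a malformed row fails with its line number."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(
                    f"{path}, line {lineno}: expected 6 motion parameters, found {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-numeric value") from exc
    if not rows:
        raise ValueError(f"{path}: empty motion file")
    return MotionParams(np.asarray(rows))


def save_behavior(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def load_behavior(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in BEHAVIOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: behavioral table missing columns {missing}")
    return validate_behavior(table)


def save_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
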