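"""Image and table I/O.

Images travel as NIfTI-1 (.nii / .nii.gz, via nibabel, affine preserved)
or 8/16-bit grayscale PNG for 2-D slices.  Label maps are integer NIfTI
volumes.  Cohort tables are CSV with columns patient_id, timepoint, group,
crs_r, feature_0..feature_{p-1}.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "read_image",
    "write_image",
    "read_labels",
    "write_labels",
    "read_cohort_csv",
    "write_cohort_csv",
    "config_hash",
    "write_json",
]


def _is_png(path) -> bool:
    return str(path).lower().endswith(".png")


def read_image(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an image; returns (data, affine).  PNG intensities are scaled
    to [0, 1]; NIfTI data are returned as stored (float volumes as
    float32/float64, affine from the header)."""
    path = str(path)
    if _is_png(path):
        from PIL import Image

        arr = np.asarray(Image.open(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
        maxv = 65535.0 if arr.dtype == np.uint16 else 255.0
        return (arr.astype(np.float32) / maxv), np.eye(4)
    img = nib.load(path)
    return np.asarray(img.dataobj), img.affine.copy()


def write_image(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    path = str(path)
    data = np.asarray(data)
    if _is_png(path):
        from PIL import Image

        scaled = np.clip(data, 0.0, 1.0)
        Image.fromarray((scaled * 65535).astype(np.uint16)).save(path)
        return
    nib.save(
        nib.Nifti1Image(
            data.astype(np.float32), np.eye(4) if affine is None else affine
        ),
        path,
    )


def read_labels(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj).astype(np.int32), img.affine.copy()


def write_labels(path, labels: np.ndarray, affine: np.ndarray | None = None) -> None:
    nib.save(
        nib.Nifti1Image(
            np.asarray(labels).astype(np.int16),
            np.eye(4) if affine is None else affine,
        ),
        str(path),
    )


def write_cohort_csv(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_cohort_csv(path):
    """Returns (X, y, patient_ids, timepoints, groups_per_scan)."""
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("feature_")]
    feat_cols.sort(key=lambda c: int(c.split("_")[1]))
    return (
        df[feat_cols].to_numpy(dtype=np.float64),
        df["crs_r"].to_numpy(dtype=np.float64),
        df["patient_id"].to_numpy(),
        df["timepoint"].to_numpy(),
        df["group"].to_numpy() if "group" in df else None,
    )


def config_hash(config: dict) -> str:
    """Stable short digest of a configuration tree."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_json(path, obj: dict) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(obj, sort_keys=True, indent=2, default=float) + "\n"
    )
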