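"""File I/O: NIfTI volumes/masks, CSV manifests and score tables.

Volumes go to ``.nii.gz`` with voxel spacing in the header; manifests and
scores are plain CSV.  Reading validates shape, spacing metadata and label
strings, and errors name the offending field.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import UNKNOWN, CalcMask, CTStack, CalcnetError, normalize_label

MANIFEST_COLUMNS = ["id", "label"]
SCORE_COLUMNS = ["id", "n_voxels", "score", "label"]


def write_stack(stack: CTStack, path: str | Path) -> Path:
    """Write a stack as NIfTI with spacing encoded in the affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(stack.spacing) + [1.0])
    img = nib.Nifti1Image(stack.values.astype(np.float32), affine)
    img.header.set_zooms(stack.spacing)
    nib.save(img, str(path))
    return path


def read_stack(path: str | Path, label: str = UNKNOWN, id: str | None = None
               ) -> CTStack:
    """Read a NIfTI volume; spacing comes from the header zooms."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise CalcnetError(
            f"{path.name}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if len(zooms) != 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise CalcnetError(f"{path.name}: missing or invalid spacing metadata "
                           f"(zooms={zooms})")
    sid = id if id is not None else path.name.removesuffix(".nii.gz").removesuffix(".nii")
    return CTStack(data, tuple(float(z) for z in zooms), label, sid)


def write_mask(mask: CalcMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path, source_id: str | None = None) -> CalcMask:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise CalcnetError(f"{path.name}: expected a 3-D mask, got {data.shape}")
    sid = source_id if source_id is not None else \
        path.name.removesuffix(".nii.gz").removesuffix(".nii")
    return CalcMask(data > 0, source_id=sid,
                    spacing=tuple(float(z) for z in img.header.get_zooms()[:3]))


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise CalcnetError(f"manifest is missing column(s) {missing}")
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest; label case variants are normalised."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise CalcnetError(f"{path.name}: manifest missing column(s) {missing}")
    df["id"] = df["id"].astype(str)
    df["label"] = [normalize_label(lab) for lab in df["label"]]
    return df


def write_scores(scores: pd.DataFrame, path: str | Path) -> Path:
    """Write (id, n_voxels, score, label) with stable float formatting so
    identical runs produce byte-identical files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise CalcnetError(f"scores table missing column(s) {missing}")
    out = scores[SCORE_COLUMNS].copy()
    out["score"] = out["score"].map(lambda v: f"{v:.9f}")
    out.to_csv(path, index=False)
    return path


def read_scores(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise CalcnetError(f"{path.name}: scores missing column(s) {missing}")
    df["id"] = df["id"].astype(str)
    df["label"] = [normalize_label(lab) for lab in df["label"]]
    df["score"] = df["score"].astype(float)
    df["n_voxels"] = df["n_voxels"].astype(int)
    return df
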