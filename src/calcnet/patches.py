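"""2.5D patch extraction: one axial/coronal/sagittal triplet per voxel.

Every voxel of a segmented calcification becomes one training or inference
example: three co-centred p x p patches cut from the orthogonal planes
through that voxel, stacked as a 3-channel image.  Intensities are clipped
to a fixed HU window and scaled to [0, 1]; positions outside the field of
view are padded with air (-1000 HU pre-normalisation).  Training sets are
optionally augmented by left-right mirroring of the whole stack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import (UNKNOWN, CalcMask, CTStack, CalcnetError,
                   EmptySegmentationError, normalize_label)

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 31
DEFAULT_HU_WINDOW = (-100.0, 1500.0)
PAD_HU = -1000.0


def normalize_hu(values: np.ndarray,
                 window: tuple[float, float] = DEFAULT_HU_WINDOW) -> np.ndarray:
    """Clip HU to `window` and scale linearly to [0, 1].

    Monotone; the window endpoints map to exactly 0 and 1.  A fixed window
    keeps attenuation semantics comparable across stacks (unlike per-stack
    min-max scaling).
    """
    lo, hi = window
    if hi <= lo:
        raise CalcnetError(f"degenerate HU window {window}")
    return (np.clip(values, lo, hi) - lo) / (hi - lo)


@dataclass
class PatchTriplet:
    """Three orthogonal normalized patches through one calcification voxel."""

    axial: np.ndarray      # (p, p) over (x, y) at fixed z
    coronal: np.ndarray    # (p, p) over (x, z) at fixed y
    sagittal: np.ndarray   # (p, p) over (y, z) at fixed x
    center_voxel: tuple[int, int, int]
    source_id: str = ""
    label: str = UNKNOWN

    def stacked(self) -> np.ndarray:
        """(3, p, p) float32 network input (axial, coronal, sagittal)."""
        return np.stack([self.axial, self.coronal, self.sagittal]).astype(np.float32)


@dataclass
class TrainingSet:
    """Materialised voxel-level examples for the 2.5D classifier.

    ``X`` is (n, 3, p, p) float32 in [0, 1]; ``y`` is 1 for stone, 0 for
    phlebolith.  ``per_calc_counts`` maps source id to its number of
    triplets (mirrored copies counted with suffix-less original id).
    """

    X: np.ndarray
    y: np.ndarray
    source_ids: np.ndarray
    centers: np.ndarray
    per_calc_counts: dict[str, int] = field(default_factory=dict)
    mirrored: bool = False
    patch_size: int = DEFAULT_PATCH_SIZE
    window: tuple[float, float] = DEFAULT_HU_WINDOW

    def __len__(self) -> int:
        return len(self.X)


def _extract_plane_patch(plane: np.ndarray, ci: int, cj: int, p: int,
                         pad_value: float) -> np.ndarray:
    out = np.full((p, p), pad_value, dtype=np.float32)
    h = p // 2
    i0, i1 = ci - h, ci + h + 1
    j0, j1 = cj - h, cj + h + 1
    si0, sj0 = max(i0, 0), max(j0, 0)
    si1, sj1 = min(i1, plane.shape[0]), min(j1, plane.shape[1])
    if si0 < si1 and sj0 < sj1:
        out[si0 - i0:si1 - i0, sj0 - j0:sj1 - j0] = plane[si0:si1, sj0:sj1]
    return out


def extract_triplet(stack: CTStack, center: tuple[int, int, int],
                    patch_size: int = DEFAULT_PATCH_SIZE,
                    window: tuple[float, float] = DEFAULT_HU_WINDOW,
                    label: str = UNKNOWN) -> PatchTriplet:
    """Cut the axial/coronal/sagittal p x p patches centred on `center`.

    Out-of-grid positions are padded with air (-1000 HU) before
    normalisation, making field-of-view truncation visually explicit.
    """
    p = int(patch_size)
    if p % 2 == 0:
        raise CalcnetError(f"patch_size must be odd, got {p}")
    x, y, z = (int(c) for c in center)
    nx, ny, nz = stack.shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise CalcnetError(f"center {center} outside grid {stack.shape}")
    axial = _extract_plane_patch(stack.values[:, :, z], x, y, p, PAD_HU)
    coronal = _extract_plane_patch(stack.values[:, y, :], x, z, p, PAD_HU)
    sagittal = _extract_plane_patch(stack.values[x, :, :], y, z, p, PAD_HU)
    return PatchTriplet(
        axial=normalize_hu(axial, window).astype(np.float32),
        coronal=normalize_hu(coronal, window).astype(np.float32),
        sagittal=normalize_hu(sagittal, window).astype(np.float32),
        center_voxel=(x, y, z), source_id=stack.id, label=normalize_label(label))


def _triplets_for(stack: CTStack, mask: CalcMask, patch_size: int,
                  window: tuple[float, float], label: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    centers = mask.voxel_indices()
    X = np.empty((len(centers), 3, patch_size, patch_size), dtype=np.float32)
    for k, c in enumerate(centers):
        X[k] = extract_triplet(stack, tuple(c), patch_size, window, label).stacked()
    return X, centers


def build_training_set(items, patch_size: int = DEFAULT_PATCH_SIZE,
                       mirror: bool = True,
                       window: tuple[float, float] = DEFAULT_HU_WINDOW
                       ) -> TrainingSet:
    """Build the voxel-level training set from (stack, mask, label) triples.

    One triplet per mask voxel; with ``mirror`` on, every stack/mask pair is
    additionally flipped left-right and contributes a second triplet per
    voxel with the same label, so the triplet count is exactly twice the
    total voxel count.  Stacks with an empty mask are skipped with a warning.
    """
    xs, ys, ids, cs = [], [], [], []
    counts: dict[str, int] = {}
    for stack, mask, label in items:
        lab = normalize_label(label)
        if mask.voxel_count == 0:
            logger.warning("skipping %s: empty segmentation", stack.id)
            continue
        variants = [(stack, mask)]
        if mirror:
            variants.append((stack.mirrored_lr(), mask.mirrored_lr()))
        total = 0
        for s, m in variants:
            X, centers = _triplets_for(s, m, patch_size, window, lab)
            xs.append(X)
            ys.append(np.full(len(X), 1 if lab == "stone" else 0, dtype=np.int8))
            ids.append(np.full(len(X), stack.id, dtype=object))
            cs.append(centers)
            total += len(X)
        counts[stack.id] = total
    if xs:
        X = np.concatenate(xs)
        y = np.concatenate(ys)
        source_ids = np.concatenate(ids)
        centers = np.concatenate(cs)
    else:
        X = np.empty((0, 3, patch_size, patch_size), dtype=np.float32)
        y = np.empty(0, dtype=np.int8)
        source_ids = np.empty(0, dtype=object)
        centers = np.empty((0, 3), dtype=int)
    return TrainingSet(X, y, source_ids, centers, counts, mirror,
                       patch_size, window)


TRAINING_SET_FORMAT = 1


def save_training_set(ts: TrainingSet, directory) -> None:
    """Persist a training set: compressed tensors plus a CSV index.

    Layout: ``triplets.npz`` (X, y), ``index.csv`` (triplet id, source id,
    label, center voxel) and ``meta.json`` (format version, patch size,
    normalisation window, mirror flag).
    """
    import json
    from pathlib import Path

    import pandas as pd
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(d / "triplets.npz", X=ts.X, y=ts.y)
    pd.DataFrame({
        "triplet": np.arange(len(ts)),
        "source_id": ts.source_ids,
        "label": np.where(ts.y == 1, "stone", "phlebolith"),
        "x": ts.centers[:, 0], "y": ts.centers[:, 1], "z": ts.centers[:, 2],
    }).to_csv(d / "index.csv", index=False)
    (d / "meta.json").write_text(json.dumps({
        "format": TRAINING_SET_FORMAT, "patch_size": ts.patch_size,
        "window": list(ts.window), "mirrored": ts.mirrored,
        "per_calc_counts": ts.per_calc_counts}, indent=2))


def load_training_set(directory) -> TrainingSet:
    import json
    from pathlib import Path

    import pandas as pd
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    if meta.get("format") != TRAINING_SET_FORMAT:
        raise CalcnetError(
            f"unsupported training-set format {meta.get('format')!r}")
    with np.load(d / "triplets.npz") as z:
        X, y = z["X"], z["y"]
    idx = pd.read_csv(d / "index.csv")
    return TrainingSet(X, y.astype(np.int8),
                       idx["source_id"].to_numpy(dtype=object),
                       idx[["x", "y", "z"]].to_numpy(),
                       dict(meta["per_calc_counts"]), meta["mirrored"],
                       int(meta["patch_size"]), tuple(meta["window"]))


def build_inference_set(stack: CTStack, mask: CalcMask,
                        patch_size: int = DEFAULT_PATCH_SIZE,
                        window: tuple[float, float] = DEFAULT_HU_WINDOW
                        ) -> tuple[np.ndarray, np.ndarray]:
    """One triplet per mask voxel, no mirroring, label unknown.

    Returns (X, centers) with X of shape (n_voxels, 3, p, p).
    """
    if mask.voxel_count == 0:
        raise EmptySegmentationError(
            f"empty segmentation for stack {stack.id or '<unnamed>'}")
    return _triplets_for(stack, mask, int(patch_size), window, UNKNOWN)
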