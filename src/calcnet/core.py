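"""Core containers and errors shared across the pipeline.

Axis convention: arrays are indexed ``[x, y, z]`` with x = left-right,
y = anterior-posterior, z = cranio-caudal.  The three cardinal planes are

* axial    — fixed z, shape (nx, ny)
* coronal  — fixed y, shape (nx, nz)
* sagittal — fixed x, shape (ny, nz)

Left-right mirroring flips axis 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STONE = "stone"
PHLEBOLITH = "phlebolith"
UNKNOWN = "unknown"
LABELS = (STONE, PHLEBOLITH)


class CalcnetError(ValueError):
    """Base class for pipeline errors."""


class EmptySegmentationError(CalcnetError):
    """No voxel reached the attenuation threshold (non-calcified stack)."""


class SizingError(CalcnetError):
    """Requested phantom geometry does not fit the 5 x 5 x 5 cm cube."""


def normalize_label(label: str) -> str:
    """Map case variants ('Stone', 'PHLEBOLITH') to canonical lowercase."""
    s = str(label).strip().lower()
    if s not in (STONE, PHLEBOLITH, UNKNOWN):
        raise CalcnetError(f"unknown label {label!r}; expected one of {LABELS}")
    return s


@dataclass
class CTStack:
    """A non-contrast CT sub-volume centred on one pelvic calcification.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Attenuation in Hounsfield units.
    spacing : tuple of float
        Voxel edge lengths (mm) along (x, y, z).
    label : str
        ``"stone"``, ``"phlebolith"`` or ``"unknown"``.
    id : str
        Stable identifier used in manifests and score files.

    The study geometry is a 5 x 5 x 5 cm cube: 50 voxels per axis at
    1 x 1 x 1 mm.  Anisotropic spacing is accepted; all mm computations
    honour it.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: str = UNKNOWN
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise CalcnetError(f"stack must be 3-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise CalcnetError("stack contains non-finite attenuation values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise CalcnetError(f"invalid voxel spacing {self.spacing}")
        self.label = normalize_label(self.label)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def mirrored_lr(self) -> "CTStack":
        """Left-right mirror image (flip along x)."""
        return CTStack(self.values[::-1].copy(), self.spacing, self.label,
                       self.id + "_lr" if self.id else "")


@dataclass
class CalcMask:
    """Boolean segmentation of one calcification, aligned to its stack.

    Produced by threshold + component selection + hole filling; a single
    26-connected component whose non-filled voxels all had source HU at or
    above the segmentation threshold.
    """

    values: np.ndarray
    source_id: str = ""
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise CalcnetError(f"mask must be 3-D, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def voxel_indices(self) -> np.ndarray:
        """(n, 3) integer array of the mask's true voxels."""
        return np.argwhere(self.values)

    def mirrored_lr(self) -> "CalcMask":
        return CalcMask(self.values[::-1].copy(), self.source_id, self.spacing)
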