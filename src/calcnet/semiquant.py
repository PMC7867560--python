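"""Semi-quantitative comparator: size + attenuation cutoff classification.

Automates the manual workflow it stands in for: re-slice the 1-mm stack to
5-mm slices (plain averaging, as an MPR viewer would), take caliper-style
lengths of the three principal axes of the segmented calcification,
convert to an ellipsoid volume W*L*H*pi/6, measure mean attenuation in a
circular ROI at the calcification centre on the 5-mm image, and classify:
a calcification is a phlebolith only if it is both small (volume at or
below the cutoff) and low-attenuating (mean HU at or below the cutoff);
otherwise it is called a stone.

The published volume cutoff appears both as 171 mm^3 and 173 mm^3 in the
source material; 171 is the default here and the value is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import PHLEBOLITH, STONE, CalcMask, CTStack, CalcnetError

HU_CUTOFF = 643.0
VOLUME_CUTOFF_MM3 = 171.0
ROI_DIAMETER_FRACTION = 0.6
ROI_MIN_DIAMETER_VOX = 3.0
WINDOW_SETTINGS = {"width": 300, "level": 40}  # display metadata only


@dataclass
class SemiQuantMeasurement:
    """Automated surrogate of the manual caliper + ROI measurements."""

    W: float
    L: float
    H: float
    volume: float
    mean_hu: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if min(self.W, self.L, self.H) <= 0:
            raise CalcnetError("principal-axis lengths must be positive")
        expected = ellipsoid_volume(self.W, self.L, self.H)
        if not math.isclose(self.volume, expected, rel_tol=1e-9):
            raise CalcnetError(
                f"volume {self.volume} inconsistent with axes "
                f"({self.W}, {self.L}, {self.H}) -> {expected}")


def make_5mm_mpr(stack: CTStack) -> CTStack:
    """Average groups of five consecutive 1-mm slices into 5-mm slices.

    Requires 1-mm slice spacing; a slice count not divisible by five is
    padded by replicating the last slice.  In-plane grid is unchanged.
    """
    sx, sy, sz = stack.spacing
    if not math.isclose(sz, 1.0, abs_tol=1e-6):
        raise CalcnetError(f"5-mm MPR expects 1-mm slice spacing, got {sz}")
    v = stack.values
    nz = v.shape[2]
    rem = (-nz) % 5
    if rem:
        v = np.concatenate([v, np.repeat(v[:, :, -1:], rem, axis=2)], axis=2)
    out = v.reshape(v.shape[0], v.shape[1], -1, 5).mean(axis=3)
    return CTStack(out, (sx, sy, 5.0), stack.label, stack.id)


def measure_axes(mask: CalcMask,
                 spacing: tuple[float, float, float] | None = None
                 ) -> tuple[float, float, float]:
    """Lengths (mm) of the three principal axes of the mask's voxel cloud.

    Principal directions come from the eigenvectors of the second-moment
    tensor of the voxel centres (in mm); each length is the full extent of
    the cloud along that direction plus the voxel footprint projected onto
    it, so a single voxel at 1-mm spacing measures (1, 1, 1).  Returned in
    descending order.
    """
    sp = np.asarray(spacing if spacing is not None else mask.spacing, dtype=float)
    coords = mask.voxel_indices() * sp
    if len(coords) == 0:
        raise CalcnetError("cannot measure axes of an empty mask")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    _, vecs = np.linalg.eigh(cov)
    lengths = []
    for k in range(3):
        v = vecs[:, k]
        proj = centered @ v
        # voxel footprint along the direction, capped at one voxel so
        # oblique directions are not over-counted
        voxel_footprint = min(float(np.abs(v) @ sp), float(sp.max()))
        lengths.append(float(proj.max() - proj.min()) + voxel_footprint)
    return tuple(sorted(lengths, reverse=True))


def ellipsoid_volume(W: float, L: float, H: float) -> float:
    """Ellipsoid volume from the three principal-axis lengths: W*L*H*pi/6."""
    if min(W, L, H) <= 0:
        raise CalcnetError("axis lengths must be positive")
    return W * L * H * math.pi / 6.0


def mean_attenuation_roi(stack_5mm: CTStack, mask: CalcMask,
                         roi_fraction: float = ROI_DIAMETER_FRACTION) -> float:
    """Mean HU in a circular ROI at the calcification centre on 5-mm images.

    The ROI sits on the 5-mm slice containing the mask centroid, centred at
    the in-plane centroid; its diameter is `roi_fraction` of the mask's
    largest in-plane extent on that slab (at least 3 voxels), emulating a
    PACS ROI-circle placed in the centre of the calcification.
    """
    if mask.voxel_count == 0:
        raise CalcnetError("cannot measure attenuation of an empty mask")
    sx, sy, _ = mask.spacing
    if not math.isclose(stack_5mm.spacing[2], 5.0, abs_tol=1e-6):
        raise CalcnetError("mean_attenuation_roi expects a 5-mm MPR stack")
    vox = mask.voxel_indices()
    centroid = vox.mean(axis=0)
    slab = int(np.clip(centroid[2] * mask.spacing[2] // 5.0, 0,
                       stack_5mm.shape[2] - 1))
    in_slab = vox[(vox[:, 2] * mask.spacing[2] >= slab * 5.0)
                  & (vox[:, 2] * mask.spacing[2] < (slab + 1) * 5.0)]
    if len(in_slab) == 0:
        in_slab = vox
    xy = in_slab[:, :2] * np.array([sx, sy])
    span = np.ptp(xy, axis=0)
    largest = float(np.hypot(*span)) if len(xy) > 1 else 0.0
    diameter = max(roi_fraction * largest, ROI_MIN_DIAMETER_VOX * min(sx, sy))
    cx, cy = xy.mean(axis=0) if len(xy) else centroid[:2] * np.array([sx, sy])

    nx, ny = stack_5mm.shape[:2]
    gx = np.arange(nx)[:, None] * stack_5mm.spacing[0]
    gy = np.arange(ny)[None, :] * stack_5mm.spacing[1]
    in_roi = (gx - cx) ** 2 + (gy - cy) ** 2 <= (diameter / 2.0) ** 2
    if not in_roi.any():  # ROI smaller than one pixel: take the centre pixel
        in_roi[int(round(cx / stack_5mm.spacing[0])),
               int(round(cy / stack_5mm.spacing[1]))] = True
    return float(stack_5mm.values[:, :, slab][in_roi].mean())


def semiquant_classify(mean_hu: float, volume: float,
                       hu_cutoff: float = HU_CUTOFF,
                       vol_cutoff: float = VOLUME_CUTOFF_MM3) -> str:
    """Phlebolith iff mean HU <= hu_cutoff AND volume <= vol_cutoff."""
    if not (math.isfinite(mean_hu) and math.isfinite(volume)):
        raise CalcnetError("mean_hu and volume must be finite")
    if mean_hu <= hu_cutoff and volume <= vol_cutoff:
        return PHLEBOLITH
    return STONE


def measure_stack(stack: CTStack, mask: CalcMask) -> SemiQuantMeasurement:
    """Full comparator measurement chain for one stack."""
    W, L, H = measure_axes(mask)
    mpr = make_5mm_mpr(stack)
    return SemiQuantMeasurement(
        W=W, L=L, H=H, volume=ellipsoid_volume(W, L, H),
        mean_hu=mean_attenuation_roi(mpr, mask),
        source_id=stack.id or mask.source_id)
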