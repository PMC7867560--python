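"""Calcification segmentation: HU threshold, component selection, hole filling.

The segmentation is deliberately simple — voxels at or above 250 HU, the
single 26-connected component nearest the cube centre, then volumetric hole
filling — because that is all the downstream per-voxel classifier needs.
Background connectivity for hole filling is 6-connected, the standard dual
of 26-connected foreground.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import CalcMask, CTStack, CalcnetError, EmptySegmentationError

DEFAULT_THRESHOLD_HU = 250.0

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def threshold_segment(stack: CTStack, threshold: float = DEFAULT_THRESHOLD_HU
                      ) -> np.ndarray:
    """Boolean grid, true exactly where HU >= threshold.

    Raises EmptySegmentationError when nothing reaches the threshold,
    signalling a stack without a calcification.
    """
    mask = stack.values >= threshold
    if not mask.any():
        raise EmptySegmentationError(
            f"no voxel reaches {threshold} HU in stack {stack.id or '<unnamed>'}")
    return mask


def select_component(mask: np.ndarray) -> np.ndarray:
    """Keep the single 26-connected component nearest the cube centre.

    Ties on centre distance go to the larger component, then to the lowest
    lexicographic centroid.  Each stack is assumed to be curated around one
    calcification; extra components are stray high-attenuation structures.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptySegmentationError("cannot select a component of an empty mask")
    labels, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 1:
        return mask.copy()
    center = (np.array(mask.shape) - 1) / 2.0
    centroids = np.array(ndimage.center_of_mass(mask, labels, range(1, n + 1)))
    sizes = ndimage.sum_labels(mask, labels, range(1, n + 1))
    dist = np.linalg.norm(centroids - center, axis=1)
    order = sorted(range(n), key=lambda i: (round(dist[i], 9), -sizes[i],
                                            tuple(centroids[i])))
    return labels == order[0] + 1


def fill_holes(mask: np.ndarray, source_id: str = "",
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> CalcMask:
    """Fill interior cavities of a single-component mask (3-D, 6-connected
    background), mirroring the morphologic hole filling applied after
    thresholding.  Idempotent; only ever adds voxels."""
    mask = np.asarray(mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    return CalcMask(filled, source_id=source_id, spacing=spacing)


def segment_stack(stack: CTStack, threshold: float = DEFAULT_THRESHOLD_HU
                  ) -> CalcMask:
    """Full segmentation chain: threshold -> nearest component -> fill holes."""
    mask = threshold_segment(stack, threshold)
    comp = select_component(mask)
    return fill_holes(comp, source_id=stack.id, spacing=stack.spacing)
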