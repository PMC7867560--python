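"""Calcification-level scoring: average the per-voxel softmax outputs.

Each voxel of the segmented calcification is classified independently from
its patch triplet; the calcification's final score is the arithmetic mean
of the per-voxel stone probabilities, thresholded at 0.5 (ties called
stone — the clinically safer direction, since missing a ureteral stone
costs more than flagging a phlebolith).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import PHLEBOLITH, STONE, CalcMask, CTStack
from ..patches import DEFAULT_HU_WINDOW, DEFAULT_PATCH_SIZE, build_inference_set
from .network import STONE_INDEX, Network

DEFAULT_CUTOFF = 0.5


@dataclass
class CalcScore:
    """Per-voxel stone probabilities and the aggregated calcification call."""

    per_voxel_probs: np.ndarray
    score: float
    predicted_label: str
    source_id: str = ""

    @property
    def n_voxels(self) -> int:
        return len(self.per_voxel_probs)


def label_from_score(score: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    return STONE if score >= cutoff else PHLEBOLITH


def score_calcification(model: Network, stack: CTStack, mask: CalcMask,
                        cutoff: float = DEFAULT_CUTOFF,
                        patch_size: int | None = None,
                        window: tuple[float, float] = DEFAULT_HU_WINDOW
                        ) -> CalcScore:
    """Score one calcification: one probability per mask voxel, then mean.

    `patch_size` defaults to the model's own input size.
    """
    p = patch_size or getattr(model.spec, "patch_size", DEFAULT_PATCH_SIZE)
    X, _ = build_inference_set(stack, mask, patch_size=p, window=window)
    probs = model.predict_proba(X)[:, STONE_INDEX].astype(np.float64)
    score = float(probs.mean())
    return CalcScore(per_voxel_probs=probs, score=score,
                     predicted_label=label_from_score(score, cutoff),
                     source_id=stack.id or mask.source_id)
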