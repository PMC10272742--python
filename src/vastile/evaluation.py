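"""Pixel-wise segmentation agreement metrics.

Confusion counts are taken over every pixel of the image pair; the
four scores are

    Dice        = 2·TP / (2·TP + FP + FN)
    Accuracy    = (TP + TN) / (TP + TN + FP + FN)
    Sensitivity = TP / (TP + FN)
    Specificity = TN / (TN + FP)

Scores whose denominator is zero (e.g. sensitivity against an empty
reference) are reported missing (NaN) rather than 0 or 1, so averages
over tiles are not silently inflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_tiling import BinaryMask

__all__ = ["SegmentationScores", "segmentation_scores"]


@dataclass
class SegmentationScores:
    tp: int
    fp: int
    tn: int
    fn: int
    dice: float
    accuracy: float
    sensitivity: float
    specificity: float


def _safe(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def segmentation_scores(predicted: BinaryMask, reference: BinaryMask) -> SegmentationScores:
    """Score a predicted mask against a reference segmentation."""
    if predicted.shape != reference.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {reference.shape}")
    p, r = predicted.pixels, reference.pixels
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    tn = int(np.sum(~p & ~r))
    return SegmentationScores(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        dice=_safe(2.0 * tp, 2.0 * tp + fp + fn),
        accuracy=_safe(tp + tn, tp + tn + fp + fn),
        sensitivity=_safe(tp, tp + fn),
        specificity=_safe(tn, tn + fp),
    )
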