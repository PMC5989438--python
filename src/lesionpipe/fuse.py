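"""Union fusion of segmentation masks, cleanup, and overlap metrics.

The two probabilistic segmentations (range-midpoint mean and normal M.D)
are combined per pixel by logical OR — the additive law of probability for
the union of the two foreground events. Fusion is followed (optionally) by
keeping the largest 8-connected component and filling interior holes.

``mask_metrics`` scores a predicted mask against ground truth with pixel
accuracy ("similarity rate", in percent), Dice and Jaccard coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MaskMetrics", "fuse_union", "postprocess", "mask_metrics"]

logger = logging.getLogger(__name__)


@dataclass
class MaskMetrics:
    similarity_rate: float  # percent pixel accuracy
    dice: float
    jaccard: float


def _as_binary(m: np.ndarray, name: str = "mask") -> np.ndarray:
    m = np.asarray(m)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary {{0,1}}, found values {vals[:5]}")
    return m.astype(np.uint8)


def fuse_union(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Element-wise OR of two binary masks of equal shape."""
    a = _as_binary(a, "mask a")
    b = _as_binary(b, "mask b")
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.logical_or(a, b).astype(np.uint8)


def postprocess(
    m: np.ndarray, keep_largest: bool = True, fill_holes: bool = True
) -> np.ndarray:
    """Retain the largest 8-connected component and/or fill interior holes."""
    m = _as_binary(m)
    if m.max() == 0:
        logger.warning("postprocess called on an empty mask; returned unchanged")
        return m
    if keep_largest:
        labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
            m = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    if fill_holes:
        m = ndimage.binary_fill_holes(m).astype(np.uint8)
    return m


def mask_metrics(pred: np.ndarray, gt: np.ndarray) -> MaskMetrics:
    """Pixel accuracy (percent), Dice and Jaccard of pred vs ground truth.

    Dice and Jaccard are defined as 1 when both masks are empty.
    """
    pred = _as_binary(pred, "pred")
    gt = _as_binary(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.sum((pred == 1) & (gt == 1)))
    tn = int(np.sum((pred == 0) & (gt == 0)))
    fp = int(np.sum((pred == 1) & (gt == 0)))
    fn = int(np.sum((pred == 0) & (gt == 1)))
    total = pred.size
    similarity = 100.0 * (tp + tn) / total
    if tp + fp + fn == 0:
        dice = jaccard = 1.0
    else:
        dice = 2.0 * tp / (2 * tp + fp + fn)
        jaccard = tp / (tp + fp + fn)
    return MaskMetrics(similarity_rate=similarity, dice=dice, jaccard=jaccard)
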