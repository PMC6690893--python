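"""Training losses: soft IoU, region attraction, and their combination.

The soft IoU loss compares the un-thresholded probability map against the
binary annotation; the attraction loss penalizes probability mass missing
from the interaction region of interest (``M > gamma``).  The total loss is
``lambda1 * L_iou + (1 - lambda1) * L_attraction``; ``lambda1`` close to 1
keeps the annotation the primary target while the weight map drives local
corrections.

Gradients with respect to the soft prediction are provided analytically for
the training loop (both losses are smooth in the prediction away from the
ROI threshold set).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field_map import WeightMap, roi_mask

__all__ = [
    "LossWeights",
    "iou_loss",
    "iou_loss_grad",
    "attraction_loss",
    "attraction_loss_grad",
    "combined_loss",
    "combined_loss_grad",
]


@dataclass(frozen=True)
class LossWeights:
    """Relative weight ``lambda1`` of the IoU term in the combined loss."""

    lambda1: float = 0.68

    def __post_init__(self):
        if not 0.0 <= self.lambda1 <= 1.0:
            raise ValueError(f"lambda1 must lie in [0, 1], got {self.lambda1}")


def _check_pred(truth, pred):
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: {truth.shape} vs {pred.shape}")
    if pred.min() < 0.0 or pred.max() > 1.0:
        raise ValueError("prediction values must lie in [0, 1]")
    return truth, pred


def iou_loss(truth, pred) -> float:
    """``1 - soft IoU`` between a binary mask and a soft prediction.

    Returns 0 when both grids sum to zero (nothing to segment, nothing
    predicted).
    """
    truth, pred = _check_pred(truth, pred)
    inter = float(np.sum(truth * pred))
    union = float(np.sum(truth) + np.sum(pred) - inter)
    if union == 0.0:
        return 0.0
    return 1.0 - inter / union


def iou_loss_grad(truth, pred) -> np.ndarray:
    """d(iou_loss)/d(pred), elementwise."""
    truth, pred = _check_pred(truth, pred)
    inter = np.sum(truth * pred)
    union = np.sum(truth) + np.sum(pred) - inter
    if union == 0.0:
        return np.zeros_like(pred)
    # L = 1 - I/U; dI = t, dU = 1 - t
    return -(truth * union - inter * (1.0 - truth)) / (union * union)


def attraction_loss(map: WeightMap, gamma: float, pred) -> float:
    """Fraction of the interaction ROI left uncovered by the prediction.

    ``1 - sum((M > gamma) * pred) / sum(M > gamma)``; an empty ROI (no user
    interaction) contributes no penalty.
    """
    roi = roi_mask(map, gamma)
    pred = np.asarray(pred, dtype=np.float64)
    if roi.shape != pred.shape:
        raise ValueError(f"shape mismatch: {roi.shape} vs {pred.shape}")
    n = float(roi.sum())
    if n == 0.0:
        return 0.0
    return 1.0 - float(np.sum(roi * pred)) / n


def attraction_loss_grad(map: WeightMap, gamma: float, pred) -> np.ndarray:
    roi = roi_mask(map, gamma)
    pred = np.asarray(pred, dtype=np.float64)
    n = float(roi.sum())
    if n == 0.0:
        return np.zeros_like(pred)
    return -roi.astype(np.float64) / n


def combined_loss(truth, pred, map: WeightMap, gamma: float,
                  weights: LossWeights) -> float:
    """``lambda1 * L_iou + (1 - lambda1) * L_attraction``."""
    l1 = weights.lambda1
    return l1 * iou_loss(truth, pred) + (1.0 - l1) * attraction_loss(map, gamma, pred)


def combined_loss_grad(truth, pred, map: WeightMap, gamma: float,
                       weights: LossWeights) -> np.ndarray:
    l1 = weights.lambda1
    return l1 * iou_loss_grad(truth, pred) + (1.0 - l1) * attraction_loss_grad(
        map, gamma, pred
    )
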