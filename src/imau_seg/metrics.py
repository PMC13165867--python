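"""Segmentation metrics: Dice, IoU, precision/recall, MAE, HD95, AUC, Dice loss.

Conventions (documented because they change edge-case values):

* both masks empty -> Dice and IoU report 1.0 (perfect agreement) with the
  ``degenerate`` flag set on the report row;
* zero-denominator precision/recall, HD95 with an empty mask, and AUC with
  a single-class truth are *undefined* (``math.nan``), never 0;
* HD95 uses boundary pixels (foreground with at least one background
  4-neighbour) and exact Euclidean distance transforms, taking the 95th
  percentile of the pooled directed boundary distances in both directions;
* AUC uses the Mann–Whitney/midrank convention;
* predictions are binarized at 0.5 for counts-based metrics, matching the
  mask binarization threshold of the preprocessing stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt
from sklearn.metrics import roc_auc_score

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "dice",
    "jaccard",
    "dice_from_jaccard",
    "precision_recall",
    "mae",
    "hd95",
    "auc_roc",
    "dice_loss",
    "evaluate_pair",
    "BINARIZE_THRESHOLD",
]

BINARIZE_THRESHOLD = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """One row of every results table; NaN encodes an undefined metric."""

    dice: float = math.nan
    iou: float = math.nan
    precision: float = math.nan
    recall: float = math.nan
    mae: float = math.nan
    hd95: float = math.nan
    auc: float = math.nan
    degenerate: bool = False
    sample_id: str = ""

    def metric_names(self) -> list[str]:
        return [f.name for f in fields(self) if f.type == "float"]

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.metric_names()}


def _binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary {{0,1}}")
    return a.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    pred = _binary(pred, "pred")
    truth = _binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}"
        )
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def dice(c: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN); both-empty pairs count as perfect agreement."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def jaccard(c: ConfusionCounts) -> float:
    """TP / (TP + FP + FN); both-empty pairs count as perfect agreement."""
    denom = c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return c.tp / denom


def dice_from_jaccard(iou: float) -> float:
    return 2.0 * iou / (1.0 + iou)


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else math.nan
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    return precision, recall


def mae(prob: np.ndarray, truth: np.ndarray) -> float:
    """Mean absolute difference between a probability map and a binary mask."""
    prob = np.asarray(prob, np.float64)
    truth = np.asarray(truth, np.float64)
    if prob.shape != truth.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {truth.shape}")
    return float(np.abs(truth - prob).mean())


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one background 4-neighbour.

    Pixels outside the image count as background, so foreground touching
    the frame edge is boundary.
    """
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    return mask & ~binary_erosion(mask, cross, border_value=False)


def hd95(pred: np.ndarray, truth: np.ndarray) -> float:
    """95th percentile of symmetric boundary-to-boundary Euclidean distances."""
    pred = _binary(pred, "pred")
    truth = _binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if not pred.any() or not truth.any():
        return math.nan
    bp, bt = _boundary(pred), _boundary(truth)
    d_to_t = distance_transform_edt(~bt)[bp]
    d_to_p = distance_transform_edt(~bp)[bt]
    return float(np.percentile(np.concatenate([d_to_t, d_to_p]), 95))


def auc_roc(prob: np.ndarray, truth: np.ndarray) -> float:
    """Pixel-wise ROC AUC (midrank tie handling); NaN for single-class truth."""
    truth = np.asarray(truth).ravel()
    prob = np.asarray(prob, np.float64).ravel()
    if prob.shape != truth.shape:
        raise ValueError("shape mismatch between probability map and truth")
    if len(np.unique(truth)) < 2:
        return math.nan
    return float(roc_auc_score(truth.astype(int), prob))


def dice_loss(prob: np.ndarray, truth: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss 1 - (2*sum(p*y)+s) / (sum(p)+sum(y)+s)."""
    prob = np.asarray(prob, np.float64)
    truth = np.asarray(truth, np.float64)
    if prob.shape != truth.shape:
        raise ValueError(f"shape mismatch: {prob.shape} vs {truth.shape}")
    inter = float((prob * truth).sum())
    return 1.0 - (2.0 * inter + smooth) / (prob.sum() + truth.sum() + smooth)


def evaluate_pair(prob: np.ndarray, truth: np.ndarray,
                  sample_id: str = "",
                  threshold: float = BINARIZE_THRESHOLD) -> MetricReport:
    """Full per-image metric row from a probability map and a binary truth."""
    pred = (np.asarray(prob) > threshold).astype(np.uint8)
    c = confusion_counts(pred, truth)
    precision, recall = precision_recall(c)
    degenerate = (c.tp + c.fp + c.fn) == 0
    return MetricReport(
        dice=dice(c),
        iou=jaccard(c),
        precision=precision,
        recall=recall,
        mae=mae(prob, truth),
        hd95=hd95(pred, truth),
        auc=auc_roc(prob, truth),
        degenerate=degenerate,
        sample_id=sample_id,
    )
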