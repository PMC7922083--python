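"""Segmentation losses and overlap metrics.

Metrics are computed from an explicit pixel confusion tally:
recall = TP/(TP+FN), precision = TP/(TP+FP), IoU = TP/(TP+FP+FN),
Dice = 2TP/(2TP+FP+FN); for counts from a single pooled tally these satisfy
Dice = 2*IoU/(1+IoU).  Degenerate denominators follow the usual convention:
a metric is 1 when both masks are empty and 0 when exactly one is.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

EPS_CLIP = 1e-7


def sigmoid(x):
    """Logistic function 1 / (1 + exp(-x))."""
    return expit(x)


def bce_loss(pred, truth, reduction: str = "mean") -> float:
    """Binary cross-entropy  -sum[y log p + (1-y) log(1-p)] over pixels.

    Predictions are clipped to [EPS_CLIP, 1 - EPS_CLIP] before the logs.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    p = np.clip(pred, EPS_CLIP, 1.0 - EPS_CLIP)
    total = -np.sum(truth * np.log(p) + (1.0 - truth) * np.log1p(-p))
    return float(total / pred.size) if reduction == "mean" else float(total)


def binarize(pred, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; the boundary value is foreground."""
    if not (0.0 < threshold < 1.0 or threshold == 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    return (np.asarray(pred) >= threshold).astype(np.uint8)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def confusion(pred, truth) -> ConfusionCounts:
    """Exhaustive pixel tally of two binary masks of identical shape."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask is not binary")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def _ratio(num: int, den: int, empty_ok: bool) -> float:
    if den == 0:
        return 1.0 if empty_ok else 0.0
    return num / den


def recall(c: ConfusionCounts) -> float:
    """TP / (TP + FN)."""
    return _ratio(c.tp, c.tp + c.fn, empty_ok=c.fp == 0)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp, empty_ok=c.fn == 0)


def iou(c: ConfusionCounts) -> float:
    """TP / (TP + FP + FN) (Jaccard index)."""
    return _ratio(c.tp, c.tp + c.fp + c.fn, empty_ok=True)


def dice(c: ConfusionCounts) -> float:
    """2 TP / (2 TP + FP + FN)."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, empty_ok=True)


@dataclass
class MetricsReport:
    dice: float
    iou: float
    recall: float
    precision: float
    counts: ConfusionCounts
    aggregation: str
    n_images: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def __str__(self) -> str:
        return (
            f"Dice {self.dice:.4f}  IoU {self.iou:.4f}  "
            f"Recall {self.recall:.4f}  Precision {self.precision:.4f}"
        )


def report_from_counts(c: ConfusionCounts, aggregation: str = "global-pooled",
                       n_images: int = 1) -> MetricsReport:
    return MetricsReport(dice(c), iou(c), recall(c), precision(c), c,
                         aggregation, n_images)


def evaluate_dataset(
    preds,
    truths,
    threshold: float = 0.5,
    aggregation: str = "per-image-mean",
) -> MetricsReport:
    """Binarize, tally and aggregate metrics over paired prediction/truth maps.

    ``per-image-mean`` averages each metric over images (the comparison-
    literature norm); ``global-pooled`` sums the confusion counts first.
    """
    preds, truths = list(preds), list(truths)
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")
    if not preds:
        raise ValueError("cannot evaluate an empty dataset")
    if aggregation not in ("per-image-mean", "global-pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    per_image = [confusion(binarize(p, threshold), t) for p, t in zip(preds, truths)]
    pooled = ConfusionCounts(0, 0, 0, 0)
    for c in per_image:
        pooled = pooled + c
    if aggregation == "global-pooled":
        rep = report_from_counts(pooled, aggregation, len(per_image))
    else:
        rep = MetricsReport(
            dice=float(np.mean([dice(c) for c in per_image])),
            iou=float(np.mean([iou(c) for c in per_image])),
            recall=float(np.mean([recall(c) for c in per_image])),
            precision=float(np.mean([precision(c) for c in per_image])),
            counts=pooled,
            aggregation=aggregation,
            n_images=len(per_image),
        )
    return rep
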