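"""Detection matching and Pre / Rec / F1 / Acc metrics.

Predicted boxes are matched greedily (descending score) one-to-one
against ground-truth boxes at an IoU threshold; unmatched predictions
are false positives and unmatched truths false negatives. True
negatives only exist in anchor-classification contexts, so accuracy is
reported only when TN is meaningful; any metric with a zero denominator
is reported as undefined (None), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .losses import pairwise_iou


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass
class Metrics:
    precision: float | None
    recall: float | None
    f1: float | None
    accuracy: float | None


def match_detections(
    pred_boxes,
    true_boxes,
    scores=None,
    iou_threshold: float = 0.5,
) -> ConfusionCounts:
    """Greedy one-to-one matching of predictions to ground truth.

    Predictions are visited in descending score order (input order if no
    scores); each claims the highest-IoU unmatched truth with IoU >= the
    threshold, else counts as a false positive. TN is reported as 0
    (undefined for open-world detection).
    """
    pred = np.asarray(pred_boxes, dtype=np.float64).reshape(-1, 4)
    true = np.asarray(true_boxes, dtype=np.float64).reshape(-1, 4)
    if len(pred) == 0:
        return ConfusionCounts(fn=len(true))
    if len(true) == 0:
        return ConfusionCounts(fp=len(pred))
    order = (
        np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")
        if scores is not None
        else np.arange(len(pred))
    )
    ious = pairwise_iou(pred, true)
    matched = np.zeros(len(true), dtype=bool)
    tp = fp = 0
    for i in order:
        row = np.where(matched, -1.0, ious[i])
        j = int(row.argmax())
        if row[j] >= iou_threshold:
            matched[j] = True
            tp += 1
        else:
            fp += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=int((~matched).sum()))


def f1_score(precision: float, recall: float) -> float | None:
    """Harmonic mean ``2 P R / (P + R)``; undefined when P + R = 0."""
    if precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def metrics(counts: ConfusionCounts, with_accuracy: bool = False) -> Metrics:
    """Pre, Rec, F1 (and optionally Acc) from confusion counts."""
    pre = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    rec = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    f1 = f1_score(pre, rec) if pre is not None and rec is not None else None
    acc = None
    if with_accuracy:
        total = counts.tp + counts.tn + counts.fp + counts.fn
        acc = (counts.tp + counts.tn) / total if total > 0 else None
    return Metrics(precision=pre, recall=rec, f1=f1, accuracy=acc)


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding to the printed precision of a report."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
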