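"""Detection losses: IoU, DIoU, Smooth L1, cross-entropy, and the
composite RPN / detection-head / total losses.

All functions are plain evaluable functions (no autograd). Boxes are
``(x1, y1, x2, y2)`` with ``x2 > x1`` and ``y2 > y1``; degenerate boxes
are rejected so the enclosing-box diagonal stays positive.

The DIoU loss augments ``1 - IoU`` with a centre-distance penalty
``rho^2 / d^2``, where ``rho`` is the Euclidean distance between box
centres and ``d`` the diagonal of the minimum enclosing box. Unlike the
bare IoU loss it yields a useful value (and a descent direction) even
for disjoint boxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: probability clamp for cross-entropy
EPS = 1e-7


@dataclass(frozen=True)
class LossConfig:
    """Weights and normalisers of the composite losses.

    delta / delta_prime weight the box-regression terms of the RPN and
    head losses; n_cls is the number of sampled anchors and n_reg the
    number of positive+negative samples used for normalisation.
    """

    delta: float = 1.0
    delta_prime: float = 1.0
    n_cls: int = 1
    n_reg: int = 1

    def __post_init__(self) -> None:
        if self.delta < 0 or self.delta_prime < 0:
            raise ValueError("weights must be >= 0")
        if self.n_cls < 1 or self.n_reg < 1:
            raise ValueError("n_cls and n_reg must be >= 1")


def _check_box(box, name: str) -> tuple[float, float, float, float]:
    x1, y1, x2, y2 = (float(v) for v in box)
    if not (x2 > x1 and y2 > y1):
        raise ValueError(f"{name} box {tuple(box)} has nonpositive area")
    return x1, y1, x2, y2


def iou(box_p, box_gt) -> float:
    """Intersection over union of two boxes, in [0, 1]."""
    px1, py1, px2, py2 = _check_box(box_p, "prediction")
    gx1, gy1, gx2, gy2 = _check_box(box_gt, "ground-truth")
    iw = min(px2, gx2) - max(px1, gx1)
    ih = min(py2, gy2) - max(py1, gy1)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = (px2 - px1) * (py2 - py1) + (gx2 - gx1) * (gy2 - gy1) - inter
    return inter / union


def pairwise_iou(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """(N, M) IoU matrix for two box arrays (vectorised, no validation)."""
    a = np.asarray(boxes_a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=np.float64).reshape(-1, 4)
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = inter / union
    return np.where(union > 0, out, 0.0)


def diou_penalty(box_p, box_gt) -> float:
    """Centre-distance penalty ``rho^2 / d^2`` in [0, 1)."""
    px1, py1, px2, py2 = _check_box(box_p, "prediction")
    gx1, gy1, gx2, gy2 = _check_box(box_gt, "ground-truth")
    pcx, pcy = (px1 + px2) / 2, (py1 + py2) / 2
    gcx, gcy = (gx1 + gx2) / 2, (gy1 + gy2) / 2
    rho2 = (pcx - gcx) ** 2 + (pcy - gcy) ** 2
    ew = max(px2, gx2) - min(px1, gx1)
    eh = max(py2, gy2) - min(py1, gy1)
    d2 = ew * ew + eh * eh
    return rho2 / d2


def diou_loss(box_p, box_gt) -> float:
    """DIoU loss ``1 - IoU + rho^2 / d^2``, in [0, 2)."""
    return 1.0 - iou(box_p, box_gt) + diou_penalty(box_p, box_gt)


def smooth_l1(residual):
    """Smooth L1: ``0.5 r^2`` for |r| < 1, ``|r| - 0.5`` otherwise."""
    r = np.abs(np.asarray(residual, dtype=np.float64))
    out = np.where(r < 1.0, 0.5 * r * r, r - 0.5)
    return float(out) if out.ndim == 0 else out


def cross_entropy(p, y):
    """Binary cross-entropy ``-[y ln p + (1-y) ln(1-p)]`` with probability
    clamped into [EPS, 1-EPS] so the value is always finite."""
    p = np.clip(np.asarray(p, dtype=np.float64), EPS, 1.0 - EPS)
    y = np.asarray(y, dtype=np.float64)
    out = -(y * np.log(p) + (1.0 - y) * np.log1p(-p))
    return float(out) if out.ndim == 0 else out


def mask_loss(pred_mask, true_mask) -> float:
    """Mean per-pixel binary cross-entropy between a predicted soft mask
    and a binary ground-truth mask of the same shape."""
    pred = np.asarray(pred_mask, dtype=np.float64)
    true = np.asarray(true_mask, dtype=np.float64)
    if pred.shape != true.shape:
        raise ValueError(
            f"mask shapes differ: predicted {pred.shape} vs true {true.shape}"
        )
    return float(np.mean(cross_entropy(pred, true)))


def rpn_loss(batch, config: LossConfig = LossConfig()) -> float:
    """Composite RPN loss over a batch of anchors.

    Each batch record supplies ``p`` (predicted probability of positive),
    ``p_star`` (0/1 discriminant), and for positives ``pred_box`` /
    ``gt_box``. The classification term is the summed cross-entropy over
    all anchors divided by n_cls; the regression term is the summed DIoU
    loss over positive anchors (gated by ``p_star``) weighted
    delta / n_reg.
    """
    cls_sum = 0.0
    reg_sum = 0.0
    for rec in batch:
        p_star = int(rec["p_star"])
        cls_sum += cross_entropy(rec["p"], p_star)
        if p_star == 1:
            if rec.get("gt_box") is None or rec.get("pred_box") is None:
                raise ValueError("positive anchor is missing its pred/gt box")
            reg_sum += diou_loss(rec["pred_box"], rec["gt_box"])
    return cls_sum / config.n_cls + config.delta * reg_sum / config.n_reg


def head_loss(sample, config: LossConfig = LossConfig()) -> float:
    """Detection-head loss for one ROI sample.

    ``sample`` supplies ``class_probs`` (probability vector over classes,
    index 0 = background), ``u`` (true class label), ``pred_box`` /
    ``gt_box``, and for foreground samples ``pred_mask`` / ``true_mask``
    of the true class. The regression and mask terms are gated by the
    indicator [u >= 1]; the mask term is the mean per-pixel binary
    cross-entropy on the class-specific mask.
    """
    probs = np.asarray(sample["class_probs"], dtype=np.float64)
    u = int(sample["u"])
    cls = float(cross_entropy(probs[u], 1.0))
    if u >= 1:
        reg = config.delta_prime * diou_loss(sample["pred_box"], sample["gt_box"])
        m = mask_loss(sample["pred_mask"], sample["true_mask"])
    else:
        reg = 0.0
        m = 0.0
    return cls + reg + m


def total_loss(rpn_value: float, head_value: float) -> float:
    """Overall model loss: RPN loss plus detection-head loss."""
    if rpn_value < 0 or head_value < 0:
        raise ValueError("loss components must be >= 0")
    return rpn_value + head_value
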