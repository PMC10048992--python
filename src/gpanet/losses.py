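"""Training losses and evaluation metrics.

Scalar reference implementations (plain floats / numpy) live here alongside
the tensor CIoU used inside the detector training loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor
from .detection import BoxXYXY, Detection, iou

__all__ = [
    "SmoothedLabel",
    "ConfusionCounts",
    "smooth_labels",
    "ce_loss",
    "ciou",
    "ciou_loss",
    "ciou_loss_tensor",
    "accuracy",
    "precision_recall",
    "match_detections",
    "average_precision",
    "confusion_matrix",
    "LOG_FLOOR",
]

LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class SmoothedLabel:
    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=np.float64)
        if p.min() < 0 or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("SmoothedLabel must be a probability vector")
        object.__setattr__(self, "probs", p)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")


def smooth_labels(class_index: int, eps: float, n_classes: int) -> SmoothedLabel:
    """y' = (1 - eps) * onehot + eps * uniform(1/K)."""
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must lie in [0, 1)")
    if not 0 <= class_index < n_classes:
        raise ValueError("class_index out of range")
    probs = np.full(n_classes, eps / n_classes, dtype=np.float64)
    probs[class_index] += 1.0 - eps
    return SmoothedLabel(probs)


def ce_loss(pred_probs, target) -> float:
    """Cross entropy -sum(t * log(p)) with a 1e-12 log floor."""
    p = np.asarray(pred_probs, dtype=np.float64)
    if p.min() < -1e-9 or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("pred_probs must be a probability distribution")
    t = target.probs if isinstance(target, SmoothedLabel) else np.asarray(target, dtype=np.float64)
    return float(-(t * np.log(np.maximum(p, LOG_FLOOR))).sum())


def ciou(pred, target) -> float:
    """Complete IoU: IoU - rho^2/c^2 - alpha*v."""
    p = pred if isinstance(pred, BoxXYXY) else BoxXYXY(*pred)
    t = target if isinstance(target, BoxXYXY) else BoxXYXY(*target)
    overlap = iou(p, t)
    (pcx, pcy), (tcx, tcy) = p.center, t.center
    rho2 = (pcx - tcx) ** 2 + (pcy - tcy) ** 2
    ex1, ey1 = min(p.x1, t.x1), min(p.y1, t.y1)
    ex2, ey2 = max(p.x2, t.x2), max(p.y2, t.y2)
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
    v = (4.0 / math.pi**2) * (math.atan(t.width / t.height) - math.atan(p.width / p.height)) ** 2
    alpha = 0.0 if v == 0.0 else v / (1.0 - overlap + v)
    return overlap - rho2 / c2 - alpha * v


def ciou_loss(pred, target) -> float:
    """1 - CIoU; zero iff the boxes coincide."""
    return 1.0 - ciou(pred, target)


def ciou_loss_tensor(pred: Tensor, target: np.ndarray) -> Tensor:
    """Vectorized differentiable CIoU loss; pred (N, 4) xyxy, target (N, 4).

    alpha is treated as a constant within the step, matching the original
    CIoU formulation.  Returns per-box losses, (N,).
    """
    pred = as_tensor(pred)
    tgt = np.asarray(target, dtype=np.float32)
    px1, py1, px2, py2 = (pred[:, i] for i in range(4))
    tx1, ty1, tx2, ty2 = (Tensor(tgt[:, i]) for i in range(4))
    iw = px2.minimum(tx2) - px1.maximum(tx1)
    ih = py2.minimum(ty2) - py1.maximum(ty1)
    inter = iw.clip_min(0.0) * ih.clip_min(0.0)
    area_p = (px2 - px1) * (py2 - py1)
    area_t = (tx2 - tx1) * (ty2 - ty1)
    union = area_p + area_t - inter
    overlap = inter / union.clip_min(1e-9)
    pcx, pcy = (px1 + px2) * 0.5, (py1 + py2) * 0.5
    tcx, tcy = (tx1 + tx2) * 0.5, (ty1 + ty2) * 0.5
    rho2 = (pcx - tcx) ** 2 + (pcy - tcy) ** 2
    ew = px2.maximum(tx2) - px1.minimum(tx1)
    eh = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = (ew**2 + eh**2).clip_min(1e-9)
    ang = ((tx2 - tx1) / (ty2 - ty1)).arctan() - ((px2 - px1) / (py2 - py1).clip_min(1e-6)).arctan()
    v = ang**2 * (4.0 / math.pi**2)
    alpha = Tensor(v.data / np.maximum(1.0 - overlap.data + v.data, 1e-9))  # constant
    return 1.0 - overlap + rho2 / c2 + alpha * v


def accuracy(counts: ConfusionCounts) -> float:
    total = counts.TP + counts.TN + counts.FP + counts.FN
    if total == 0:
        raise ValueError("accuracy undefined for all-zero counts")
    return (counts.TP + counts.TN) / total


def precision_recall(counts: ConfusionCounts) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); degenerate denominators give 0."""
    p = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP > 0 else 0.0
    r = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN > 0 else 0.0
    return p, r


def match_detections(preds: list[Detection], truth, iou_thresh: float):
    """Greedy one-to-one matching of score-sorted predictions to truth boxes.

    ``truth`` is a list of (BoxXYXY, class_id).  Returns a boolean TP flag per
    prediction (in score order) plus the ordered predictions.
    """
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    matched = [False] * len(truth)
    flags = []
    ordered = []
    for i in order:
        d = preds[i]
        best, best_iou = -1, iou_thresh
        for j, (tbox, tcls) in enumerate(truth):
            if matched[j] or tcls != d.class_id:
                continue
            ov = iou(d.box, tbox)
            if ov >= best_iou:
                best, best_iou = j, ov
        if best >= 0:
            matched[best] = True
            flags.append(True)
        else:
            flags.append(False)
        ordered.append(d)
    return flags, ordered


def _ap_from_flags(flags: list[bool], n_truth: int) -> float:
    """All-point interpolated area under the precision envelope."""
    if n_truth == 0:
        raise ValueError("AP undefined with no truth boxes")
    tp = np.cumsum(np.asarray(flags, dtype=np.float64))
    fp = np.cumsum(~np.asarray(flags, dtype=bool))
    recall = tp / n_truth
    precision = tp / np.maximum(tp + fp, 1)
    mrec = np.concatenate([[0.0], recall, [recall[-1] if len(recall) else 0.0]])
    mpre = np.concatenate([[1.0], precision, [0.0]])
    for i in range(len(mpre) - 2, -1, -1):
        mpre[i] = max(mpre[i], mpre[i + 1])
    return float(np.sum((mrec[1:] - mrec[:-1]) * mpre[1:]))


def average_precision(preds: list[Detection], truth, iou_thresh: float = 0.5) -> float:
    """Macro-mean AP over classes present in the ground truth.

    Classes with no truth boxes are excluded from the mean.
    """
    if not 0.0 < iou_thresh < 1.0:
        raise ValueError("iou_thresh must lie in (0, 1)")
    classes = sorted({cls for _, cls in truth})
    if not classes:
        raise ValueError("AP undefined: ground truth is empty")
    aps = []
    for cls in classes:
        cls_truth = [(b, c) for b, c in truth if c == cls]
        cls_preds = [d for d in preds if d.class_id == cls]
        if not cls_preds:
            aps.append(0.0)
            continue
        flags, _ = match_detections(cls_preds, cls_truth, iou_thresh)
        aps.append(_ap_from_flags(flags, len(cls_truth)))
    return float(np.mean(aps))


def confusion_matrix(pred_classes, true_classes, n_classes: int) -> np.ndarray:
    """K x K counts; entry (i, j) = true class i predicted as class j."""
    pred = np.asarray(pred_classes, dtype=int)
    true = np.asarray(true_classes, dtype=int)
    if pred.shape != true.shape:
        raise ValueError("prediction/label length mismatch")
    if len(pred) and (pred.min() < 0 or pred.max() >= n_classes or true.min() < 0 or true.max() >= n_classes):
        raise ValueError("class id out of range")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (true, pred), 1)
    return mat
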