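"""Box geometry, hard/soft NMS and a minimal grid-anchor detection head.

Soft-NMS uses the linear decay rule: a box overlapping the current top box
by at least ``Nt`` keeps score ``s * (1 - IoU)`` instead of being removed;
boxes whose decayed score falls below ``score_floor`` are dropped.  Both NMS
variants are applied per class with deterministic tie-breaking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, as_tensor

__all__ = [
    "BoxXYXY",
    "Detection",
    "iou",
    "hard_nms",
    "soft_nms",
    "DetectionHead",
    "decode_detections",
    "encode_box",
    "decode_box",
    "read_yolo_labels",
    "write_yolo_labels",
    "detections_to_json",
]


@dataclass(frozen=True)
class BoxXYXY:
    """Corner-encoded axis-aligned box in pixels; x2 > x1, y2 > y1."""

    x1: float
    y1: float
    x2: float
    y2: float

    def __post_init__(self):
        vals = (self.x1, self.y1, self.x2, self.y2)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("box coordinates must be finite")
        if self.x2 <= self.x1 or self.y2 <= self.y1:
            raise ValueError(f"degenerate box {vals}: require x2 > x1 and y2 > y1")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))


@dataclass(frozen=True)
class Detection:
    """A scored, classified box — the unit NMS and AP operate on."""

    box: BoxXYXY
    score: float
    class_id: int = 0

    def __post_init__(self):
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


def _coerce(box) -> BoxXYXY:
    return box if isinstance(box, BoxXYXY) else BoxXYXY(*box)


def iou(a, b) -> float:
    """Intersection over union; negative intersection extents clamp to 0."""
    a, b = _coerce(a), _coerce(b)
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    s1 = max(iw, 0.0) * max(ih, 0.0)
    s2 = a.area + b.area - s1
    return s1 / s2


def _ordered(dets: list[Detection]) -> list[Detection]:
    """Deterministic processing order: score desc, then x1, y1, input index."""
    return [
        d
        for _, d in sorted(
            enumerate(dets), key=lambda t: (-t[1].score, t[1].box.x1, t[1].box.y1, t[0])
        )
    ]


def hard_nms(dets: list[Detection], nt: float = 0.5) -> list[Detection]:
    """Classic NMS: remove every box overlapping a kept box by IoU >= Nt."""
    if not 0.0 < nt < 1.0:
        raise ValueError("Nt must lie in (0, 1)")
    kept: list[Detection] = []
    for cls in sorted({d.class_id for d in dets}):
        pool = _ordered([d for d in dets if d.class_id == cls])
        while pool:
            top = pool.pop(0)
            kept.append(top)
            pool = [d for d in pool if iou(top.box, d.box) < nt]
    return _ordered(kept)


def soft_nms(dets: list[Detection], nt: float = 0.5, score_floor: float = 0.001) -> list[Detection]:
    """Linear-decay Soft-NMS; never increases a score."""
    if not 0.0 < nt < 1.0:
        raise ValueError("Nt must lie in (0, 1)")
    if not 0.0 <= score_floor < 1.0:
        raise ValueError("score_floor must lie in [0, 1)")
    kept: list[Detection] = []
    for cls in sorted({d.class_id for d in dets}):
        pool = [(d.box, d.score, i) for i, d in enumerate(dets) if d.class_id == cls]
        while pool:
            pool.sort(key=lambda t: (-t[1], t[0].x1, t[0].y1, t[2]))
            box, score, idx = pool.pop(0)
            kept.append(Detection(box, score, cls))
            nxt = []
            for b, s, i in pool:
                ov = iou(box, b)
                if ov >= nt:
                    s = s * (1.0 - ov)
                if s >= score_floor:
                    nxt.append((b, s, i))
            pool = nxt
    return _ordered(kept)


# ---------------------------------------------------------------------------
# Grid-anchor detection head
# ---------------------------------------------------------------------------


def _logit(p: float) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    return math.log(p / (1 - p))


def encode_box(box: BoxXYXY, gx: int, gy: int, anchor: tuple[float, float], stride: float):
    """Inverse of :func:`decode_box`: box -> raw (tx, ty, tw, th).

    Sizes use the bounded convention w = anchor * (2 * sigmoid(tw))^2, so the
    encodable range is (0, 4 * anchor)."""
    cx, cy = box.center
    tx = _logit(cx / stride - gx)
    ty = _logit(cy / stride - gy)
    tw = _logit(0.5 * math.sqrt(box.width / anchor[0]))
    th = _logit(0.5 * math.sqrt(box.height / anchor[1]))
    return tx, ty, tw, th


def decode_box(t, gx: int, gy: int, anchor: tuple[float, float], stride: float) -> BoxXYXY:
    tx, ty, tw, th = (float(v) for v in t)
    cx = (gx + 1.0 / (1.0 + math.exp(-tx))) * stride
    cy = (gy + 1.0 / (1.0 + math.exp(-ty))) * stride
    w = anchor[0] * (2.0 / (1.0 + math.exp(-tw))) ** 2
    h = anchor[1] * (2.0 / (1.0 + math.exp(-th))) ** 2
    return BoxXYXY(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


class DetectionHead(nn.Module):
    """1x1 convolution predicting (tx, ty, tw, th, obj, classes) per anchor."""

    def __init__(self, in_channels: int, anchors: list[tuple[float, float]], n_classes: int, stride: int, rng=None):
        super().__init__()
        if not anchors:
            raise ValueError("anchors must be non-empty")
        self.anchors = [tuple(map(float, a)) for a in anchors]
        self.n_classes = n_classes
        self.stride = stride
        out_ch = len(self.anchors) * (5 + n_classes)
        self.conv = nn.Conv2d(in_channels, out_ch, 1, rng=rng)
        # small init keeps initial boxes anchor-shaped at their cells, which
        # keeps CIoU gradients alive
        self.conv.weight.data *= 0.05

    def forward(self, features: Tensor) -> Tensor:
        """Raw predictions, (N, A, 5 + K, S, S)."""
        raw = self.conv(as_tensor(features))
        n, _, s1, s2 = raw.shape
        return raw.reshape(n, len(self.anchors), 5 + self.n_classes, s1, s2)


def decode_detections(raw: np.ndarray, anchors, n_classes: int, stride: float, score_thresh: float = 0.0, image_size=None) -> list[Detection]:
    """Decode one image's raw grid (A, 5+K, S, S) into image-space detections.

    Score = sigmoid(objectness) * softmax(class logits).  Every cell/anchor
    yields its best-class detection (S*S*A raw detections at thresh 0).
    """
    a, _, sh, sw = raw.shape
    dets = []
    for ai in range(a):
        for gy in range(sh):
            for gx in range(sw):
                v = raw[ai, :, gy, gx]
                obj = 1.0 / (1.0 + math.exp(-float(v[4])))
                logits = v[5:].astype(np.float64)
                e = np.exp(logits - logits.max())
                probs = e / e.sum()
                cls = int(np.argmax(probs))
                score = obj * float(probs[cls])
                if score < score_thresh:
                    continue
                box = decode_box(v[:4], gx, gy, anchors[ai], stride)
                if image_size is not None:
                    x1 = min(max(box.x1, 0.0), image_size - 1.0)
                    y1 = min(max(box.y1, 0.0), image_size - 1.0)
                    x2 = min(max(box.x2, x1 + 1e-3), float(image_size))
                    y2 = min(max(box.y2, y1 + 1e-3), float(image_size))
                    box = BoxXYXY(x1, y1, x2, y2)
                dets.append(Detection(box, min(score, 1.0), cls))
    return dets


# ---------------------------------------------------------------------------
# YOLO-format label I/O
# ---------------------------------------------------------------------------


def write_yolo_labels(path, entries, img_w: int, img_h: int, with_score=False) -> None:
    """Write ``class cx cy w h [score]`` lines, coordinates normalized to [0,1]."""
    lines = []
    for entry in entries:
        if isinstance(entry, Detection):
            box, cls, score = entry.box, entry.class_id, entry.score
        else:
            box, cls = _coerce(entry[0]), int(entry[1])
            score = None
        cx, cy = box.center
        fields = [str(cls), f"{cx / img_w:.6f}", f"{cy / img_h:.6f}", f"{box.width / img_w:.6f}", f"{box.height / img_h:.6f}"]
        if with_score:
            fields.append(f"{score:.6f}")
        lines.append(" ".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path, img_w: int, img_h: int):
    """Read YOLO label lines; returns [(BoxXYXY, class_id)] or, when a sixth
    score column is present, [Detection]."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            cls = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:5])
            box = BoxXYXY(
                (cx - w / 2) * img_w,
                (cy - h / 2) * img_h,
                (cx + w / 2) * img_w,
                (cy + h / 2) * img_h,
            )
            if len(parts) >= 6:
                out.append(Detection(box, float(parts[5]), cls))
            else:
                out.append((box, cls))
    return out


def detections_to_json(dets: list[Detection], path=None):
    payload = [
        {
            "box": [d.box.x1, d.box.y1, d.box.x2, d.box.y2],
            "score": d.score,
            "class_id": d.class_id,
        }
        for d in dets
    ]
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    return payload
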