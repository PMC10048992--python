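"""Run configuration, training/evaluation loops and the ablation harness."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import nn
from .autograd import Tensor, concatenate, no_grad
from .backbone import CSPBackbone, StageConfig
from .detection import DetectionHead, decode_detections, hard_nms, read_yolo_labels, soft_nms
from .losses import (average_precision, ciou_loss_tensor, confusion_matrix,
                     match_detections, smooth_labels)
from .model import GPANet, build_variant, classification_loss

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "paper_profile", "load_config", "save_config",
           "load_classification_data", "load_detection_data",
           "train_classifier", "train_detector", "evaluate_classifier",
           "evaluate_detector", "ablate", "save_checkpoint", "load_checkpoint"]


@dataclass
class RunConfig:
    task: str = "classify"
    data_dir: str = "data"
    out_dir: str = "runs/run0"
    variant: str = "full"
    stages: list = field(default_factory=lambda: [[1, 8, 16, 2], [1, 16, 24, 2], [1, 24, 32, 2], [1, 32, 48, 2]])
    image_size: int = 64
    n_classes: int = 8
    epochs: int = 10
    batch_size: int = 16
    lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-4
    cosine_period: int = 10
    eps_smooth: float = 0.1
    node_cap: int = 16
    graph_dim: int = 24
    nt: float = 0.5
    score_floor: float = 0.001
    score_thresh: float = 0.25
    iou_thresh: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("epochs", "batch_size", "lr", "cosine_period", "image_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def stage_configs(self) -> list[StageConfig]:
        return [StageConfig(n, ci, co, g) for n, ci, co, g in self.stages]


def paper_profile() -> RunConfig:
    """The published training regime (448 px, batch 128, SGD, cosine period 20).

    Kept as a named preset; far beyond the toy test surface.
    """
    return RunConfig(image_size=448, batch_size=128, epochs=150, cosine_period=20,
                     lr=0.1, n_classes=200)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Data loading
# ---------------------------------------------------------------------------


def _load_image(path) -> np.ndarray:
    arr = np.asarray(Image.open(path), dtype=np.float32) / 255.0
    return (arr - 0.5).transpose(2, 0, 1)  # CHW, centred


def load_classification_data(data_dir) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Load {split: (images NCHW, labels)} from a written dataset."""
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    splits: dict[str, list] = {}
    for item in manifest["items"]:
        splits.setdefault(item["split"], []).append(item)
    out = {}
    for split, items in splits.items():
        imgs = np.stack([_load_image(data_dir / it["path"]) for it in items])
        labels = np.array([it["class"] for it in items], dtype=int)
        out[split] = (imgs, labels)
    return out


def load_detection_data(data_dir) -> dict[str, list]:
    """Load {split: [(image NCHW, [(BoxXYXY, cls)])]} from a written dataset."""
    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    size = None
    out: dict[str, list] = {}
    for item in manifest["items"]:
        img = _load_image(data_dir / item["path"])
        size = img.shape[-1]
        truth = read_yolo_labels(data_dir / item["labels"], size, size)
        out.setdefault(item["split"], []).append((img, truth))
    return out


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: nn.Module, path, meta: dict | None = None) -> None:
    path = Path(path)
    np.savez(path, **model.named_state())
    if meta is not None:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(meta, fh, indent=2)


def load_checkpoint(model: nn.Module, path) -> nn.Module:
    state = np.load(Path(path), allow_pickle=False)
    model.load_state({k: state[k] for k in state.files})
    return model


# ---------------------------------------------------------------------------
# Classification training
# ---------------------------------------------------------------------------


def _smoothed_targets(labels: np.ndarray, n_classes: int, eps: float) -> np.ndarray:
    return np.stack([smooth_labels(int(c), eps, n_classes).probs for c in labels]).astype(np.float32)


def train_classifier(cfg: RunConfig, data=None, model: GPANet | None = None) -> dict:
    """Train a GPA-Net variant; returns a log dict and writes artifacts.

    The log carries per-epoch train loss, validation accuracy, learning rate
    and the best checkpoint path.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = load_classification_data(cfg.data_dir)
    if "train" not in data:
        raise FileNotFoundError("classification dataset has no train split")
    x_train, y_train = data["train"]
    val_split = "test" if "test" in data else "train"
    x_val, y_val = data[val_split]
    if model is None:
        model = build_variant(cfg.variant, cfg.n_classes, seed=cfg.seed,
                              stage_configs=cfg.stage_configs(),
                              node_cap=cfg.node_cap, graph_dim=cfg.graph_dim)
    targets = _smoothed_targets(y_train, cfg.n_classes, cfg.eps_smooth)
    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    log = {"variant": cfg.variant, "epochs": [], "best_acc": 0.0, "seed": cfg.seed}
    best_acc = -1.0
    ckpt = out_dir / "checkpoint.npz"
    for epoch in range(cfg.epochs):
        opt.lr = nn.cosine_annealing_lr(cfg.lr, epoch, cfg.cosine_period, min_lr=cfg.lr * 0.01)
        order = rng.permutation(len(x_train))
        model.train()
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) < 2:
                continue  # batch-norm needs more than one sample
            probs = model(Tensor(x_train[idx]))
            loss = classification_loss(probs, targets[idx])
            if not math.isfinite(float(loss.data)):
                raise RuntimeError(f"divergent loss at epoch {epoch}: {float(loss.data)}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        _calibrate(model, x_train, cfg.batch_size)
        acc = _classify_accuracy(model, x_val, y_val, cfg.batch_size)
        log["epochs"].append({"epoch": epoch, "loss": float(np.mean(losses)),
                              "val_acc": acc, "lr": opt.lr})
        logger.info("epoch %d loss %.4f val_acc %.3f", epoch, np.mean(losses), acc)
        if acc > best_acc:
            best_acc = acc
            save_checkpoint(model, ckpt, meta={"variant": cfg.variant,
                                               "n_classes": cfg.n_classes,
                                               "val_acc": acc, "epoch": epoch})
    log["best_acc"] = best_acc
    log["checkpoint"] = str(ckpt)
    with open(out_dir / "train_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return log


def _calibrate(model, images: np.ndarray, batch_size: int, cap: int = 128) -> None:
    """Precise-BN pass over (up to ``cap``) training images."""
    step = max(1, int(np.ceil(len(images) / cap)))
    subset = images[::step]  # strided, so every class is represented
    batches = [subset[i : i + batch_size] for i in range(0, len(subset), batch_size)]
    batches = [b for b in batches if len(b) >= 2]
    nn.calibrate_batchnorm(model, lambda b: model(Tensor(b)), batches)


def _classify_accuracy(model: GPANet, images, labels, batch_size: int) -> float:
    model.eval()
    preds = []
    with no_grad():
        for start in range(0, len(images), batch_size):
            preds.append(model.predict(Tensor(images[start : start + batch_size])))
    return float(np.mean(np.concatenate(preds) == labels))


def evaluate_classifier(cfg: RunConfig, data=None, model: GPANet | None = None) -> dict:
    """Accuracy + confusion matrix report (JSON + PNG heat map)."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = load_classification_data(cfg.data_dir)
    if model is None:
        model = build_variant(cfg.variant, cfg.n_classes, seed=cfg.seed,
                              stage_configs=cfg.stage_configs(),
                              node_cap=cfg.node_cap, graph_dim=cfg.graph_dim)
        load_checkpoint(model, Path(cfg.out_dir) / "checkpoint.npz")
    split = "test" if "test" in data else "train"
    images, labels = data[split]
    model.eval()
    preds = []
    with no_grad():
        for start in range(0, len(images), cfg.batch_size):
            preds.append(model.predict(Tensor(images[start : start + cfg.batch_size])))
    preds = np.concatenate(preds)
    mat = confusion_matrix(preds, labels, cfg.n_classes)
    report = {"split": split, "acc": float(np.mean(preds == labels)),
              "confusion": mat.tolist(), "n": int(len(labels))}
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _render_confusion_png(mat, out_dir / "confusion.png")
    return report


def _render_confusion_png(mat: np.ndarray, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(mat, cmap="viridis")
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Detection training / evaluation
# ---------------------------------------------------------------------------

ANCHORS = [(24.0, 18.0), (44.0, 32.0)]


class Detector(nn.Module):
    """Backbone trunk (through stage 3) + grid-anchor head, stride 8."""

    def __init__(self, cfg: RunConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.backbone = CSPBackbone(cfg.stage_configs(), rng=rng)
        ch3 = cfg.stage_configs()[2].out_channels
        self.head = DetectionHead(ch3, ANCHORS, cfg.n_classes, stride=8, rng=rng)

    def forward(self, x):
        stages = self.backbone(x)
        feat = next(fm for fm in stages if fm.stage_index == 3)
        return self.head(feat.values)


def _assign_targets(truth, grid: int, stride: float, n_classes: int):
    """Per-image target assignment: (cells, anchor ids, target boxes, classes)."""
    from .detection import iou as box_iou, BoxXYXY

    rows = []
    for box, cls in truth:
        cx, cy = box.center
        gx = min(int(cx // stride), grid - 1)
        gy = min(int(cy // stride), grid - 1)
        best_a, best_iou = 0, -1.0
        for ai, (aw, ah) in enumerate(ANCHORS):
            shape_a = BoxXYXY(0, 0, aw, ah)
            shape_b = BoxXYXY(0, 0, box.width, box.height)
            ov = box_iou(shape_a, shape_b)
            if ov > best_iou:
                best_a, best_iou = ai, ov
        rows.append((best_a, gy, gx, box, cls))
    return rows


def train_detector(cfg: RunConfig, data=None, model: Detector | None = None) -> dict:
    """Optimize objectness BCE + class CE + CIoU box loss on the toy head."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = load_detection_data(cfg.data_dir)
    if "train" not in data:
        raise FileNotFoundError("detection dataset has no train split")
    train = data["train"]
    model = model or Detector(cfg)
    opt = nn.SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay, clip_norm=5.0)
    rng = np.random.default_rng(cfg.seed)
    log = {"epochs": [], "seed": cfg.seed}
    for epoch in range(cfg.epochs):
        opt.lr = nn.cosine_annealing_lr(cfg.lr, epoch, cfg.cosine_period, min_lr=cfg.lr * 0.01)
        order = rng.permutation(len(train))
        model.train()
        comps = {"obj": [], "cls": [], "box": []}
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) < 2:
                continue
            imgs = np.stack([train[i][0] for i in idx])
            raw = model(Tensor(imgs))  # (B, A, 5+K, S, S)
            b, a, _, s, _ = raw.shape
            obj_target = np.zeros((b, a, s, s), dtype=np.float32)
            sel_b, sel_a, sel_y, sel_x, tboxes, tcls = [], [], [], [], [], []
            for bi, i in enumerate(idx):
                for ai, gy, gx, box, cls in _assign_targets(train[i][1], s, model.head.stride, cfg.n_classes):
                    obj_target[bi, ai, gy, gx] = 1.0
                    sel_b.append(bi); sel_a.append(ai); sel_y.append(gy); sel_x.append(gx)
                    tboxes.append([box.x1, box.y1, box.x2, box.y2]); tcls.append(cls)
            obj_logits = raw[:, :, 4, :, :]
            t = Tensor(obj_target)
            # numerically stable BCE-with-logits, positives upweighted so the
            # handful of object cells is not swamped by background cells
            bce = (obj_logits.clip_min(0.0) - obj_logits * t
                   + (1.0 + (-obj_logits.abs()).exp()).log())
            pos_frac = float(obj_target.mean())
            pos_w = Tensor((1.0 + obj_target * (0.5 / max(pos_frac, 1e-6) - 1.0)).astype(np.float32))
            obj_loss = (bce * pos_w).mean()
            if sel_b:
                sel = (np.array(sel_b), np.array(sel_a), np.array(sel_y), np.array(sel_x))
                picked = raw[sel[0], sel[1], :, sel[2], sel[3]]  # (M, 5+K)
                cls_logp = picked[:, 5:].softmax(axis=-1).clip_min(1e-12).log()
                onehot = np.zeros((len(tcls), cfg.n_classes), dtype=np.float32)
                onehot[np.arange(len(tcls)), tcls] = 1.0
                cls_loss = -(Tensor(onehot) * cls_logp).sum(axis=-1).mean()
                stride = float(model.head.stride)
                anchors_wh = np.array(ANCHORS, dtype=np.float32)[np.array(sel_a)]
                cx = (Tensor(np.array(sel_x, dtype=np.float32)) + picked[:, 0].sigmoid()) * stride
                cy = (Tensor(np.array(sel_y, dtype=np.float32)) + picked[:, 1].sigmoid()) * stride
                pw = Tensor(anchors_wh[:, 0]) * (picked[:, 2].sigmoid() * 2.0) ** 2.0
                ph = Tensor(anchors_wh[:, 1]) * (picked[:, 3].sigmoid() * 2.0) ** 2.0
                pred_xyxy = concatenate(
                    [(cx - pw * 0.5).reshape(-1, 1), (cy - ph * 0.5).reshape(-1, 1),
                     (cx + pw * 0.5).reshape(-1, 1), (cy + ph * 0.5).reshape(-1, 1)], axis=1)
                box_loss = ciou_loss_tensor(pred_xyxy, np.array(tboxes)).mean()
            else:
                cls_loss = Tensor(0.0)
                box_loss = Tensor(0.0)
            loss = obj_loss * 2.0 + cls_loss + box_loss * 3.0
            if not math.isfinite(float(loss.data)):
                raise RuntimeError(f"divergent detector loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            comps["obj"].append(float(obj_loss.data))
            comps["cls"].append(float(cls_loss.data))
            comps["box"].append(float(box_loss.data))
        entry = {k: float(np.mean(v)) for k, v in comps.items()}
        entry["epoch"] = epoch
        log["epochs"].append(entry)
        logger.info("det epoch %d obj %.4f cls %.4f box %.4f", epoch,
                    entry["obj"], entry["cls"], entry["box"])
    _calibrate(model, np.stack([im for im, _ in train]), cfg.batch_size, cap=64)
    ckpt = out_dir / "detector.npz"
    save_checkpoint(model, ckpt, meta={"n_classes": cfg.n_classes})
    log["checkpoint"] = str(ckpt)
    with open(out_dir / "det_train_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return log


def evaluate_detector(cfg: RunConfig, data=None, model: Detector | None = None,
                      nms: str = "soft") -> dict:
    """Decode -> NMS -> greedy matching; reports P, R and macro AP."""
    if data is None:
        data = load_detection_data(cfg.data_dir)
    if model is None:
        model = Detector(cfg)
        load_checkpoint(model, Path(cfg.out_dir) / "detector.npz")
    split = "test" if "test" in data else "train"
    model.eval()
    all_preds, all_truth = [], []
    n_match, n_pred, n_truth = 0, 0, 0
    for img, truth in data[split]:
        with no_grad():
            raw = model(Tensor(img[None])).data[0]
        dets = decode_detections(raw, ANCHORS, cfg.n_classes, model.head.stride,
                                 score_thresh=cfg.score_thresh,
                                 image_size=img.shape[-1])
        if nms == "soft":
            dets = soft_nms(dets, nt=cfg.nt, score_floor=cfg.score_floor)
        elif nms == "hard":
            dets = hard_nms(dets, nt=cfg.nt)
            dets = [d for d in dets if d.score >= cfg.score_floor]
        else:
            raise ValueError("nms must be 'soft' or 'hard'")
        flags, _ = match_detections(dets, truth, cfg.iou_thresh)
        n_match += sum(flags)
        n_pred += len(dets)
        n_truth += len(truth)
        all_preds.append(dets)
        all_truth.append(truth)
    precision = n_match / n_pred if n_pred else 0.0
    recall = n_match / n_truth if n_truth else 0.0
    # offset boxes per image so cross-image matches are impossible
    ap_preds, ap_truth = [], []
    offset = 0.0
    from .detection import BoxXYXY, Detection

    for dets, truth in zip(all_preds, all_truth):
        for d in dets:
            ap_preds.append(Detection(BoxXYXY(d.box.x1 + offset, d.box.y1, d.box.x2 + offset, d.box.y2), d.score, d.class_id))
        for b, c in truth:
            ap_truth.append((BoxXYXY(b.x1 + offset, b.y1, b.x2 + offset, b.y2), c))
        offset += 10000.0
    ap = average_precision(ap_preds, ap_truth, cfg.iou_thresh) if ap_truth else 0.0
    return {"split": split, "nms": nms, "P": precision, "R": recall, "AP": ap,
            "n_pred": n_pred, "n_truth": n_truth}


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------


def ablate(cfg: RunConfig, data=None) -> list[dict]:
    """Train all four variants under identical seed/budget; returns the table."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = load_classification_data(cfg.data_dir)
    table = []
    for name in ("backbone", "backbone+cta", "backbone+gfe", "full"):
        sub = dataclasses.replace(cfg, variant=name, out_dir=str(out_dir / name.replace("+", "_")))
        log = train_classifier(sub, data=data)
        table.append({"variant": name, "val_acc": log["best_acc"]})
        logger.info("ablation %s -> %.3f", name, log["best_acc"])
    with open(out_dir / "ablation.json", "w") as fh:
        json.dump(table, fh, indent=2)
    return table
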