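"""Synthetic fine-grained "bird" data: classification crops and cluttered
multi-object detection scenes with exact ground truth.

All classes share one body template; classes differ only in small part
parameters (beak, wing stripes, eye ring) whose continuous spread shrinks as
``similarity`` approaches 1, so high-similarity libraries are genuinely
fine-grained: global color statistics are nearly class-independent while the
parts remain discriminative.  Every operation is deterministic per seed.
"""

from __future__ import annotations

import colorsys
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .detection import BoxXYXY, write_yolo_labels

__all__ = [
    "SpeciesSpec",
    "SceneSpec",
    "AugmentFlags",
    "make_species_library",
    "part_parameter_distance",
    "render_crop",
    "render_scene",
    "write_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesSpec:
    """Parametric description of one synthetic species."""

    class_id: int
    body_hue: float
    body_axes: tuple[float, float]  # ellipse semi-axes, px at the 64-px base size
    beak_size: float  # px at base size
    beak_hue: float
    wing_stripe_count: int
    eye_ring: bool

    def __post_init__(self):
        if self.body_axes[0] <= 0 or self.body_axes[1] <= 0:
            raise ValueError("body axes must be positive")
        if not (0.0 <= self.body_hue <= 1.0 and 0.0 <= self.beak_hue <= 1.0):
            raise ValueError("hues must lie in [0, 1]")
        if self.wing_stripe_count < 0:
            raise ValueError("stripe count must be >= 0")

    @property
    def part_vector(self) -> np.ndarray:
        """Continuous part parameters used for inter-class distance."""
        return np.array(
            [self.beak_size, 10.0 * self.beak_hue, 10.0 * self.body_hue,
             self.body_axes[0], self.body_axes[1]]
        )


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one detection scene."""

    image_size: int = 160
    n_instances: int = 3
    occlusion_prob: float = 0.3
    clutter_level: float = 1.0
    scale_range: tuple[int, int] = (28, 56)
    seed: int = 0
    cluster_prob: float = 0.5  # chance an instance is placed next to the previous one

    def __post_init__(self):
        if not 0.0 <= self.occlusion_prob <= 1.0:
            raise ValueError("occlusion_prob must lie in [0, 1]")
        if self.clutter_level < 0:
            raise ValueError("clutter_level must be >= 0")
        if self.scale_range[0] < 16 or self.scale_range[1] > self.image_size:
            raise ValueError("scale_range must fit the image")


@dataclass(frozen=True)
class AugmentFlags:
    flip: bool = False
    shift: bool = False
    lighting: bool = False


def make_species_library(n_classes: int, similarity: float, seed: int = 0) -> list[SpeciesSpec]:
    """Build ``n_classes`` species sharing a body template.

    ``similarity`` in [0, 1]: 0 gives coarse-grained classes (hue and part
    spread maximal), 1 collapses continuous differences toward zero.  The
    discrete part attributes (stripe count, eye ring) always differ between
    classes so the task stays well-posed.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if not 0.0 <= similarity <= 1.0:
        raise ValueError("similarity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    spread = 1.0 - similarity
    base_hue = float(rng.uniform(0.05, 0.45))
    base_beak_hue = float(rng.uniform(0.05, 0.15))
    base_axes = np.array([14.0, 9.0])
    library = []
    for i in range(n_classes):
        hue_off = float(rng.uniform(-0.3, 0.3))
        beak_off = float(rng.uniform(-0.05, 0.05))
        axes_off = rng.uniform(-0.2, 0.2, size=2)
        beak_len = 5.0 + 1.2 * (i % 3) + spread * float(rng.uniform(0.0, 4.0))
        library.append(
            SpeciesSpec(
                class_id=i,
                body_hue=float(np.clip(base_hue + spread * hue_off, 0.0, 1.0)),
                body_axes=tuple(base_axes * (1.0 + spread * axes_off)),
                beak_size=beak_len,
                beak_hue=float(np.clip(base_beak_hue + spread * beak_off + 0.015 * i, 0.0, 1.0)),
                wing_stripe_count=1 + (i // 2) % 4,
                eye_ring=bool(i % 2),
            )
        )
    return library


def part_parameter_distance(library: list[SpeciesSpec]) -> float:
    """Mean pairwise Euclidean distance between continuous part parameters."""
    vecs = np.stack([s.part_vector for s in library])
    n = len(vecs)
    dists = [np.linalg.norm(vecs[i] - vecs[j]) for i in range(n) for j in range(i + 1, n)]
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# Rasterization (pure numpy; deterministic)
# ---------------------------------------------------------------------------


def _hsv(h, s, v):
    return np.array(colorsys.hsv_to_rgb(h % 1.0, s, v))


def _ellipse(h, w, cx, cy, ax, ay):
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - cx) / max(ax, 1e-6)) ** 2 + ((yy - cy) / max(ay, 1e-6)) ** 2 <= 1.0


def _render_instance(spec: SpeciesSpec, size: int):
    """Draw one bird on a size x size canvas; returns (float RGB, object mask,
    part masks).  Fully deterministic in (spec, size)."""
    s = size / 64.0
    img = np.zeros((size, size, 3), dtype=np.float64)
    ax, ay = spec.body_axes[0] * s, spec.body_axes[1] * s
    cx, cy = 0.48 * size, 0.58 * size
    body = _ellipse(size, size, cx, cy, ax, ay)
    body_col = _hsv(spec.body_hue, 0.55, 0.62)
    img[body] = body_col

    # tail: shared across classes
    tail = _ellipse(size, size, cx - ax * 1.0, cy - ay * 0.3, ax * 0.35, ay * 0.35)
    img[tail] = body_col * 0.85
    # head
    rh = max(0.62 * ay, 2.0)
    hx, hy = cx + 0.78 * ax, cy - 1.05 * ay
    head = _ellipse(size, size, hx, hy, rh, rh)
    img[head] = body_col * 1.12
    # beak: horizontal triangle off the head
    bl = spec.beak_size * s
    yy, xx = np.mgrid[0:size, 0:size]
    x0, tip = hx + rh * 0.55, hx + rh * 0.55 + bl
    half_h = np.maximum(0.0, 0.35 * bl * (1.0 - (xx - x0) / max(bl, 1e-6)))
    beak = (xx >= x0) & (xx <= tip) & (np.abs(yy - hy) <= half_h)
    img[beak] = _hsv(spec.beak_hue, 0.85, 0.85)
    # eye (+ optional ring)
    ex, ey = hx + rh * 0.25, hy - rh * 0.2
    re = max(0.22 * rh, 1.0)
    ring = None
    if spec.eye_ring:
        ring = _ellipse(size, size, ex, ey, re + max(1.5 * s, 1.0), re + max(1.5 * s, 1.0))
        img[ring & head] = np.array([0.95, 0.95, 0.9])
    eye = _ellipse(size, size, ex, ey, re, re)
    img[eye] = np.array([0.05, 0.05, 0.05])
    # wing stripes: dark vertical bands on the body
    stripes = np.zeros_like(body)
    k = spec.wing_stripe_count
    if k > 0:
        xs = cx - 0.55 * ax + (np.arange(k) + 0.5) / k * 0.9 * ax
        width = max(1.0 * s, 1.0)
        for sx in xs:
            band = body & (np.abs(xx - sx) <= width) & (np.abs(yy - cy) <= 0.75 * ay)
            stripes |= band
        img[stripes] = body_col * 0.45
    mask = body | tail | head | beak | eye | (ring & head if ring is not None else False)
    parts = {"body": body, "beak": beak, "eye": eye, "stripes": stripes, "head": head}
    return img, mask, parts


def _value_noise(rng: np.random.Generator, size: int, cells: int = 8) -> np.ndarray:
    """Bilinearly upsampled random grid — cheap Perlin-like value noise."""
    grid = rng.random((cells + 1, cells + 1))
    t = np.linspace(0.0, cells, size, endpoint=False)
    i = np.floor(t).astype(int)
    f = t - i
    g = grid[np.ix_(i, i)]
    gx = grid[np.ix_(i, i + 1)]
    gy = grid[np.ix_(i + 1, i)]
    gxy = grid[np.ix_(i + 1, i + 1)]
    fx, fy = f[None, :], f[:, None]
    return (g * (1 - fx) * (1 - fy) + gx * fx * (1 - fy) + gy * (1 - fx) * fy + gxy * fx * fy)


def _background(rng: np.random.Generator, size: int, clutter: float) -> np.ndarray:
    """Cluttered background: tinted value noise, a gradient, foliage strokes."""
    hue = float(rng.uniform(0.2, 0.4))
    base = _hsv(hue, 0.35, 0.5)
    noise = _value_noise(rng, size, cells=max(4, size // 16))
    img = base[None, None, :] * (0.6 + 0.8 * noise[:, :, None])
    grad = np.linspace(0.85, 1.15, size)[:, None, None]
    img = img * grad
    n_strokes = int(round(10 * clutter))
    for _ in range(n_strokes):
        x0, y0 = rng.uniform(0, size, 2)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.1, 0.4) * size
        npts = max(int(length), 2)
        xs = (x0 + np.cos(angle) * np.linspace(0, length, npts)).astype(int)
        ys = (y0 + np.sin(angle) * np.linspace(0, length, npts)).astype(int)
        valid = (xs >= 0) & (xs < size) & (ys >= 0) & (ys < size)
        col = _hsv(hue + rng.uniform(-0.1, 0.1), 0.5, rng.uniform(0.2, 0.45))
        thickness = int(rng.integers(1, 3))
        for dx in range(-thickness + 1, thickness):
            xv = np.clip(xs[valid] + dx, 0, size - 1)
            img[ys[valid], xv] = col
    return np.clip(img, 0.0, 1.0)


def render_crop(spec: SpeciesSpec, size: int = 64, augment: AugmentFlags | None = None,
                seed: int = 0, return_masks: bool = False):
    """Render a single classification crop (uint8 RGB, H x W x 3).

    Without augmentation the bird is centred to within a 2-px margin.
    """
    if size < 32:
        raise ValueError("size must be >= 32")
    augment = augment or AugmentFlags()
    rng = np.random.default_rng(seed)
    img = _background(rng, size, clutter=0.6)
    inst, mask, parts = _render_instance(spec, size)
    dx = dy = 0
    if augment.shift:
        dx, dy = (int(v) for v in rng.integers(-size // 10, size // 10 + 1, 2))
        inst = np.roll(inst, (dy, dx), axis=(0, 1))
        mask = np.roll(mask, (dy, dx), axis=(0, 1))
    img[mask] = inst[mask]
    if augment.flip and rng.random() < 0.5:
        img = img[:, ::-1]
        mask = mask[:, ::-1]
    if augment.lighting:
        img = np.clip(img * rng.uniform(0.75, 1.25), 0.0, 1.0)
    out = (img * 255).round().astype(np.uint8)
    if return_masks:
        return out, {k: v for k, v in parts.items()}, mask
    return out


def render_scene(library: list[SpeciesSpec], scene: SceneSpec):
    """Render a multi-instance scene; returns (uint8 image, [(BoxXYXY, cls)]).

    Ground-truth boxes are tight to the full rendered instance extent (before
    any occlusion overlay) and clipped to image bounds.  If a sampled
    placement cannot fit after bounded retries the instance is skipped.
    """
    rng = np.random.default_rng(scene.seed)
    size = scene.image_size
    img = _background(rng, size, scene.clutter_level)
    truth: list[tuple[BoxXYXY, int]] = []
    prev_pos = None
    for _ in range(scene.n_instances):
        inst_size = int(rng.integers(scene.scale_range[0], scene.scale_range[1] + 1))
        spec = library[int(rng.integers(0, len(library)))]
        placed = False
        for _attempt in range(10):
            if prev_pos is not None and rng.random() < scene.cluster_prob:
                jitter = rng.integers(-inst_size // 2, inst_size // 2 + 1, 2)
                x0 = int(np.clip(prev_pos[0] + jitter[0], 0, size - inst_size))
                y0 = int(np.clip(prev_pos[1] + jitter[1], 0, size - inst_size))
            else:
                if size - inst_size <= 0:
                    continue
                x0 = int(rng.integers(0, size - inst_size + 1))
                y0 = int(rng.integers(0, size - inst_size + 1))
            placed = True
            break
        if not placed:
            logger.warning("could not place instance of size %d; skipping", inst_size)
            continue
        inst, mask, _ = _render_instance(spec, inst_size)
        region = img[y0 : y0 + inst_size, x0 : x0 + inst_size]
        region[mask] = inst[mask]
        ys, xs = np.nonzero(mask)
        box = BoxXYXY(
            float(np.clip(x0 + xs.min(), 0, size)),
            float(np.clip(y0 + ys.min(), 0, size)),
            float(np.clip(x0 + xs.max() + 1, 0, size)),
            float(np.clip(y0 + ys.max() + 1, 0, size)),
        )
        truth.append((box, spec.class_id))
        prev_pos = (x0, y0)
        if rng.random() < scene.occlusion_prob:
            # partial occluder: background-coloured ellipse over the instance
            ocx = x0 + inst_size * rng.uniform(0.25, 0.75)
            ocy = y0 + inst_size * rng.uniform(0.25, 0.75)
            oax = inst_size * rng.uniform(0.15, 0.3)
            oay = inst_size * rng.uniform(0.15, 0.3)
            occ = _ellipse(size, size, ocx, ocy, oax, oay)
            img[occ] = _hsv(rng.uniform(0.2, 0.4), 0.4, 0.35)
    return (np.clip(img, 0, 1) * 255).round().astype(np.uint8), truth


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------


def _split_counts(n: int, split_ratios: dict[str, float]) -> dict[str, int]:
    names = list(split_ratios)
    if abs(sum(split_ratios.values()) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    counts = {name: int(round(split_ratios[name] * n)) for name in names}
    drift = n - sum(counts.values())
    counts[names[0]] += drift
    return counts


def write_dataset(out_dir, library: list[SpeciesSpec], kind: str = "classification",
                  n_items: int = 100, split_ratios=None, image_size: int = 64,
                  seed: int = 0, scene_template: SceneSpec | None = None,
                  augment: AugmentFlags | None = None) -> dict:
    """Write a classification or detection dataset plus ``manifest.json``.

    Classification layout: ``{split}/{class_XX}/crop_NNNN.png``.
    Detection layout: ``images/{split}/scene_NNNN.png`` +
    ``labels/{split}/scene_NNNN.txt`` (YOLO ``class cx cy w h`` lines).
    Split assignment and all rendering are deterministic per seed.
    """
    out_dir = Path(out_dir)
    split_ratios = split_ratios or {"train": 0.7, "test": 0.3}
    counts = _split_counts(n_items, split_ratios)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_items)
    assignment = {}
    pos = 0
    for name in split_ratios:
        for idx in order[pos : pos + counts[name]]:
            assignment[int(idx)] = name
        pos += counts[name]

    manifest = {"kind": kind, "n_classes": len(library), "image_size": image_size,
                "seed": seed, "splits": counts, "items": []}
    for i in range(n_items):
        split = assignment[i]
        item_seed = seed * 1_000_003 + i
        if kind == "classification":
            cls = i % len(library)
            img = render_crop(library[cls], size=image_size, seed=item_seed,
                              augment=augment)
            rel = Path(split) / f"class_{cls:02d}" / f"crop_{i:04d}.png"
            dest = out_dir / rel
            dest.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(img).save(dest, format="PNG")
            manifest["items"].append({"path": str(rel), "split": split, "class": cls})
        elif kind == "detection":
            tpl = scene_template or SceneSpec(image_size=max(image_size, 96))
            scene = SceneSpec(
                image_size=tpl.image_size, n_instances=tpl.n_instances,
                occlusion_prob=tpl.occlusion_prob, clutter_level=tpl.clutter_level,
                scale_range=tpl.scale_range, cluster_prob=tpl.cluster_prob,
                seed=item_seed,
            )
            img, truth = render_scene(library, scene)
            img_rel = Path("images") / split / f"scene_{i:04d}.png"
            lbl_rel = Path("labels") / split / f"scene_{i:04d}.txt"
            (out_dir / img_rel).parent.mkdir(parents=True, exist_ok=True)
            (out_dir / lbl_rel).parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(img).save(out_dir / img_rel, format="PNG")
            write_yolo_labels(out_dir / lbl_rel, truth, scene.image_size, scene.image_size)
            manifest["items"].append(
                {"path": str(img_rel), "labels": str(lbl_rel), "split": split,
                 "n_objects": len(truth)}
            )
        else:
            raise ValueError(f"unknown dataset kind {kind!r}")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
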