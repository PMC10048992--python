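"""Cross-stage trilinear attention (CTA) pyramid.

For a stage feature map X and a companion map phi(X) produced by one extra
convolution block on the same stage, the channel relation matrix is

    Fc = rowsoftmax( msqrt( (1/WH) X^T phi(X) ) )          (C x C)

and the per-part spatial attention maps are

    Fd = spatialsoftmax( msqrt( Fc^T . phi(X) ) )          (C x HW)

where ``msqrt`` is the signed square root (power normalization).  Each of the
C rows of Fd is a nonnegative map over positions summing to 1.  The pyramid
applies this at backbone stages 2, 3 and 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from . import nn
from .autograd import Tensor, as_tensor
from .backbone import FeatureMap

__all__ = [
    "AttentionMaps",
    "RelationMatrix",
    "signed_sqrt",
    "bilinear_pool",
    "cross_channel_relation",
    "trilinear_attention",
    "CTAModule",
    "attention_pyramid",
    "render_attention_heatmap",
]


def signed_sqrt(x: Tensor) -> Tensor:
    """Elementwise sign(x) * sqrt(|x|): odd, monotone, fixes 0."""
    x = as_tensor(x)
    sign = Tensor(np.sign(x.data))
    return x.abs().sqrt() * sign


@dataclass
class AttentionMaps:
    """Per-part spatial attention, (N, C', H, W); each part map sums to 1."""

    maps: Tensor
    level: int

    def __post_init__(self):
        self.maps = as_tensor(self.maps)
        if self.maps.ndim == 3:
            self.maps = Tensor(self.maps.data[None])
        if self.maps.ndim != 4:
            raise ValueError("AttentionMaps expects (N, C', H, W)")

    @property
    def n_parts(self) -> int:
        return self.maps.shape[1]

    def validate(self, atol=1e-5) -> None:
        arr = self.maps.data
        if arr.min() < -atol:
            raise ValueError("attention maps must be nonnegative")
        sums = arr.sum(axis=(2, 3))
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("each part map must sum to 1 over positions")


@dataclass
class RelationMatrix:
    """Row-stochastic channel-relation matrix, (N, C, C)."""

    values: Tensor

    def __post_init__(self):
        self.values = as_tensor(self.values)
        if self.values.ndim == 2:
            self.values = Tensor(self.values.data[None])
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("RelationMatrix expects (N, C, C)")
        if not np.all(np.isfinite(self.values.data)):
            raise ValueError("RelationMatrix entries must be finite")


def _flat(x) -> Tensor:
    """(N, C, H, W) -> (N, C, HW) tensor view."""
    v = x.values if isinstance(x, FeatureMap) else as_tensor(x)
    if v.ndim == 3:
        v = Tensor(v.data[None]) if not v.requires_grad else v.reshape((1,) + v.shape)
    n, c, h, w = v.shape
    return v.reshape(n, c, h * w)


def bilinear_pool(xa, xb) -> Tensor:
    """Mean outer product over positions, flattened to (N, CA*CB).

    The classification head (a separate linear map) is not part of this op.
    """
    fa = xa.values if isinstance(xa, FeatureMap) else as_tensor(xa)
    fb = xb.values if isinstance(xb, FeatureMap) else as_tensor(xb)
    if fa.shape[2:] != fb.shape[2:]:
        raise ValueError("bilinear_pool requires matching spatial sizes")
    n, ca = fa.shape[:2]
    cb = fb.shape[1]
    hw = fa.shape[2] * fa.shape[3]
    a = fa.reshape(n, ca, hw)
    b = fb.reshape(n, cb, hw)
    outer = a @ b.transpose(0, 2, 1)  # (N, CA, CB)
    return (outer * (1.0 / hw)).reshape(n, ca * cb)


def cross_channel_relation(x, phi_x) -> RelationMatrix:
    """Channel-relation matrix Fc from a stage map and its companion map."""
    if isinstance(x, FeatureMap) and isinstance(phi_x, FeatureMap):
        if x.stage_index != phi_x.stage_index:
            raise ValueError("x and phi_x must come from the same backbone stage")
    a, b = _flat(x), _flat(phi_x)
    if a.shape != b.shape:
        raise ValueError("x and phi_x must share channel count and spatial size")
    hw = a.shape[2]
    raw = (a @ b.transpose(0, 2, 1)) * (1.0 / hw)  # (N, C, C)
    return RelationMatrix(signed_sqrt(raw).softmax(axis=-1))


def trilinear_attention(fc: RelationMatrix, phi_x, level: int = 0) -> AttentionMaps:
    """Project the relation matrix back onto phi(X) to get part attention."""
    fcv = fc.values if isinstance(fc, RelationMatrix) else as_tensor(fc)
    if fcv.ndim == 2:
        fcv = fcv.reshape((1,) + fcv.shape)
    phi = phi_x.values if isinstance(phi_x, FeatureMap) else as_tensor(phi_x)
    if phi.ndim == 3:
        phi = Tensor(phi.data[None]) if not phi.requires_grad else phi.reshape((1,) + phi.shape)
    n, c, h, w = phi.shape
    if fcv.shape[1] != c:
        raise ValueError("relation matrix and phi(X) disagree on channel count")
    flat = phi.reshape(n, c, h * w)
    fd = signed_sqrt(fcv.transpose(0, 2, 1) @ flat).softmax(axis=-1)
    return AttentionMaps(fd.reshape(n, c, h, w), level)


class CTAModule(nn.Module):
    """Learned CTA heads for the stage pyramid.

    Holds one companion ("phi") convolution block per pyramid level and emits
    (AttentionMaps, phi FeatureMap) pairs for stages 2-4.
    """

    def __init__(self, stage_channels: dict[int, int], rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.levels = sorted(stage_channels)
        self.phi_convs = [nn.Conv2d(stage_channels[k], stage_channels[k], 3, rng=rng) for k in self.levels]
        self.phi_bns = [nn.BatchNorm2d(stage_channels[k]) for k in self.levels]

    def phi(self, fm: FeatureMap) -> FeatureMap:
        i = self.levels.index(fm.stage_index)
        out = self.phi_bns[i](self.phi_convs[i](fm.values)).silu()
        return FeatureMap(out, fm.stage_index)

    def forward(self, stages: list[FeatureMap]):
        got = sorted(fm.stage_index for fm in stages)
        if got != self.levels:
            raise ValueError(f"expected stages {self.levels}, got {got}")
        out = []
        for fm in sorted(stages, key=lambda f: f.stage_index):
            phi = self.phi(fm)
            fc = cross_channel_relation(fm, phi)
            out.append((trilinear_attention(fc, phi, level=fm.stage_index), phi))
        return out


def attention_pyramid(stages: list[FeatureMap], seed: int = 0) -> list[AttentionMaps]:
    """Functional pyramid over stage-2/3/4 maps with a fresh seeded CTA head."""
    channels = {fm.stage_index: fm.channels for fm in stages}
    if sorted(channels) != [2, 3, 4]:
        raise ValueError("attention_pyramid requires exactly stages 2, 3 and 4")
    cta = CTAModule(channels, rng=np.random.default_rng(seed))
    cta.eval()
    return [att for att, _ in cta(stages)]


def _colormap(v: np.ndarray) -> np.ndarray:
    """Simple blue->red heat colormap for values in [0, 1], returns HxWx3."""
    v = np.clip(v, 0.0, 1.0)
    r = np.clip(1.5 * v - 0.25, 0, 1)
    g = np.clip(1.0 - np.abs(2.0 * v - 1.0), 0, 1)
    b = np.clip(1.25 - 1.5 * v, 0, 1)
    return np.stack([r, g, b], axis=-1)


def render_attention_heatmap(att: AttentionMaps, image: np.ndarray, path, part=None, alpha=0.5):
    """Blend (upsampled) attention mass onto an image and write a PNG.

    ``part=None`` renders the mean over part channels.  Non-integer scale
    factors fall back to nearest-neighbour resizing.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    h_img, w_img = img.shape[:2]
    arr = att.maps.data[0]
    mass = arr.mean(axis=0) if part is None else arr[part]
    ri = (np.arange(h_img) * mass.shape[0] // h_img).clip(0, mass.shape[0] - 1)
    ci = (np.arange(w_img) * mass.shape[1] // w_img).clip(0, mass.shape[1] - 1)
    up = mass[np.ix_(ri, ci)]
    rng_span = up.max() - up.min()
    norm = (up - up.min()) / rng_span if rng_span > 0 else np.full_like(up, 0.5)
    overlay = np.clip((1 - alpha) * img + alpha * _colormap(norm), 0.0, 1.0)
    out = (overlay * 255).round().astype(np.uint8)
    Image.fromarray(out).save(path, format="PNG")
    return out
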