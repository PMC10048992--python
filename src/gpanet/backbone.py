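"""CSP-style multi-stage convolutional backbone.

Each stage splits its input into a processed ("base") branch of ``n_blocks``
residual bottlenecks and a shortcut ("cross") branch, both entered through a
1x1 projection that halves the stage width.  The branches are concatenated,
channel-shuffled, and downsampled by a stride-2 3x3 convolution.  Stages 2-4
are exposed for the attention pyramid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, as_tensor, concatenate

__all__ = [
    "FeatureMap",
    "StageConfig",
    "channel_shuffle",
    "csp_stage",
    "CSPStage",
    "PlainStage",
    "CSPBackbone",
    "backbone_forward",
    "DEFAULT_STAGES",
]


@dataclass
class FeatureMap:
    """Activation grid in NCHW layout tagged with its backbone stage."""

    values: Tensor
    stage_index: int = 0

    def __post_init__(self):
        self.values = as_tensor(self.values)
        if self.values.ndim == 3:  # HWC convenience
            self.values = Tensor(self.values.data.transpose(2, 0, 1)[None])
        if self.values.ndim != 4:
            raise ValueError("FeatureMap expects (N, C, H, W) or (H, W, C) values")
        if not np.all(np.isfinite(self.values.data)):
            raise ValueError("FeatureMap values must be finite")

    @property
    def channels(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[2]

    @property
    def width(self) -> int:
        return self.values.shape[3]

    def hwc(self) -> np.ndarray:
        """First batch element as an H x W x C array."""
        return self.values.data[0].transpose(1, 2, 0)


@dataclass
class StageConfig:
    """Hyperparameters of one CSP stage."""

    n_blocks: int
    in_channels: int
    out_channels: int
    shuffle_groups: int = 2

    def __post_init__(self):
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be >= 0")
        if self.in_channels <= 0 or self.out_channels <= 0:
            raise ValueError("channel counts must be positive")
        if self.out_channels % 2:
            raise ValueError("out_channels must be even (two half-width branches)")
        if self.shuffle_groups <= 0 or self.out_channels % self.shuffle_groups:
            raise ValueError("shuffle_groups must divide the concatenated channel count")


# Toy-profile stage plan used by default (the published network never states
# its widths; see README).
DEFAULT_STAGES = (
    StageConfig(1, 8, 16),
    StageConfig(1, 16, 24, shuffle_groups=2),
    StageConfig(1, 24, 32),
    StageConfig(1, 32, 48),
)


def channel_shuffle(x, groups: int):
    """Deterministic channel permutation: reshape C->(g, C/g), transpose, flatten.

    Accepts a ``Tensor``/array in NCHW layout or a :class:`FeatureMap`; returns
    the same kind.  ``groups`` must divide the channel count.
    """
    if isinstance(x, FeatureMap):
        return FeatureMap(channel_shuffle(x.values, groups), x.stage_index)
    x = as_tensor(x)
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"groups={groups} does not divide C={c}")
    return x.reshape(n, groups, c // groups, h, w).transpose(0, 2, 1, 3, 4).reshape(n, c, h, w)


def shuffle_permutation(c: int, groups: int) -> np.ndarray:
    """Index map p such that shuffled[:, i] = original[:, p[i]]."""
    return np.arange(c).reshape(groups, c // groups).T.ravel()


class _Bottleneck(nn.Module):
    """3x3 residual bottleneck: 1x1 reduce, 3x3 expand, residual add."""

    def __init__(self, channels, rng, norm=True):
        super().__init__()
        hidden = max(channels // 2, 1)
        self.conv1 = nn.Conv2d(channels, hidden, 1, rng=rng)
        self.bn1 = nn.BatchNorm2d(hidden) if norm else nn.Identity()
        self.conv2 = nn.Conv2d(hidden, channels, 3, rng=rng)
        self.bn2 = nn.BatchNorm2d(channels) if norm else nn.Identity()

    def forward(self, x):
        y = self.bn1(self.conv1(x)).silu()
        y = self.bn2(self.conv2(y))
        return (y + x).silu()


class CSPStage(nn.Module):
    """One CSP stage; halves the spatial extent, emits cfg.out_channels."""

    def __init__(self, cfg: StageConfig, rng=None, norm=True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        half = cfg.out_channels // 2
        self.proj_base = nn.Conv2d(cfg.in_channels, half, 1, bias=not norm, rng=rng)
        self.proj_cross = nn.Conv2d(cfg.in_channels, half, 1, bias=not norm, rng=rng)
        self.blocks = [_Bottleneck(half, rng, norm=norm) for _ in range(cfg.n_blocks)]
        self.down = nn.Conv2d(cfg.out_channels, cfg.out_channels, 3, stride=2, pad=1, bias=not norm, rng=rng)
        self.bn_down = nn.BatchNorm2d(cfg.out_channels) if norm else nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}"
            )
        if x.shape[2] <= 1 or x.shape[3] <= 1:
            raise ValueError("degenerate input: H and W must exceed 1 before downsampling")
        base = self.proj_base(x)
        for blk in self.blocks:
            base = blk(base)
        cross = self.proj_cross(x)
        merged = channel_shuffle(concatenate([base, cross], axis=1), self.cfg.shuffle_groups)
        return self.bn_down(self.down(merged)).silu()


class PlainStage(nn.Module):
    """Non-CSP comparison stage: same blocks applied at full width."""

    def __init__(self, cfg: StageConfig, rng=None, norm=True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.proj = nn.Conv2d(cfg.in_channels, cfg.out_channels, 1, bias=not norm, rng=rng)
        self.blocks = [_Bottleneck(cfg.out_channels, rng, norm=norm) for _ in range(cfg.n_blocks)]
        self.down = nn.Conv2d(cfg.out_channels, cfg.out_channels, 3, stride=2, pad=1, bias=not norm, rng=rng)
        self.bn_down = nn.BatchNorm2d(cfg.out_channels) if norm else nn.Identity()

    def forward(self, x):
        y = self.proj(x)
        for blk in self.blocks:
            y = blk(y)
        return self.bn_down(self.down(y)).silu()


def csp_stage(x: FeatureMap, cfg: StageConfig, rng=None) -> FeatureMap:
    """Apply a freshly initialized CSP stage to a feature map (functional form)."""
    stage = CSPStage(cfg, rng=rng)
    stage.eval()
    return FeatureMap(stage(x.values), x.stage_index + 1)


class CSPBackbone(nn.Module):
    """Stem convolution followed by four CSP stages.

    ``forward`` returns the list of all stage outputs as FeatureMaps
    (stage_index 1..4); :meth:`pyramid_stages` picks stages 2-4.
    """

    def __init__(self, configs=DEFAULT_STAGES, stem_channels=None, rng=None, allow_resize=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        configs = list(configs)
        stem_channels = stem_channels or configs[0].in_channels
        if stem_channels != configs[0].in_channels:
            raise ValueError("stem output must match the first stage's in_channels")
        self.configs = configs
        self.allow_resize = allow_resize
        self.stem = nn.Conv2d(3, stem_channels, 3, rng=rng)
        self.bn_stem = nn.BatchNorm2d(stem_channels)
        self.stages = [CSPStage(cfg, rng=rng) for cfg in configs]

    @property
    def total_downsample(self) -> int:
        return 2 ** len(self.stages)

    def _check_size(self, x: np.ndarray) -> np.ndarray:
        d = self.total_downsample
        h, w = x.shape[2], x.shape[3]
        if h % d == 0 and w % d == 0:
            return x
        if not self.allow_resize:
            raise ValueError(
                f"input {h}x{w} not divisible by the downsampling factor {d}; "
                "set allow_resize=True to round up with nearest-neighbour resize"
            )
        nh, nw = ((h + d - 1) // d) * d, ((w + d - 1) // d) * d
        ri = (np.arange(nh) * h // nh).clip(0, h - 1)
        ci = (np.arange(nw) * w // nw).clip(0, w - 1)
        return x[:, :, ri][:, :, :, ci]

    def forward(self, x) -> list[FeatureMap]:
        x = as_tensor(x)
        if x.ndim == 3:
            x = Tensor(x.data[None])
        x = Tensor(self._check_size(x.data)) if not x.requires_grad else x
        y = self.bn_stem(self.stem(x)).silu()
        outputs = []
        for idx, stage in enumerate(self.stages, start=1):
            y = stage(y)
            outputs.append(FeatureMap(y, idx))
        return outputs

    def pyramid_stages(self, outputs: list[FeatureMap]) -> list[FeatureMap]:
        return [fm for fm in outputs if fm.stage_index in (2, 3, 4)]


def backbone_forward(image: np.ndarray, configs=DEFAULT_STAGES, seed: int = 0, allow_resize=False) -> list[FeatureMap]:
    """Run a seeded, freshly initialized backbone over an H x W x 3 image.

    Returns the stage-2, stage-3 and stage-4 feature maps.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    net = CSPBackbone(configs, rng=np.random.default_rng(seed), allow_resize=allow_resize)
    net.eval()
    x = img.transpose(2, 0, 1)[None]
    return net.pyramid_stages(net(x))
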