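"""Graph-based high-order feature embedding.

Attention-pooled part descriptors become graph nodes; a cosine-similarity
adjacency (plus self loops) drives one symmetric-normalized propagation step

    G = ReLU( D^{-1/2} (A + I) D^{-1/2} K W ),

and an adaptive tanh/softmax attention fuses the per-level embeddings into a
single class-probability vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, as_tensor, concatenate
from .attention import AttentionMaps
from .backbone import FeatureMap

__all__ = [
    "PartFeatureBank",
    "LevelWeights",
    "part_pooling",
    "adjacency",
    "graph_propagate",
    "level_attention",
    "fused_score",
    "GraphLevel",
    "LevelAttention",
]


@dataclass
class PartFeatureBank:
    """Node-feature matrix, (N, P, D); rows are part descriptors."""

    nodes: Tensor
    level: int = 0

    def __post_init__(self):
        self.nodes = as_tensor(self.nodes)
        if self.nodes.ndim == 2:
            self.nodes = Tensor(self.nodes.data[None]) if not self.nodes.requires_grad else self.nodes.reshape((1,) + self.nodes.shape)
        if self.nodes.ndim != 3:
            raise ValueError("PartFeatureBank expects (N, P, D) nodes")
        if self.nodes.shape[1] < 1:
            raise ValueError("need at least one node")
        if not np.all(np.isfinite(self.nodes.data)):
            raise ValueError("node features must be finite")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[1]

    @property
    def dim(self) -> int:
        return self.nodes.shape[2]


@dataclass
class LevelWeights:
    """Per-level fusion weights, (N, L); nonnegative, rows sum to 1."""

    I: Tensor

    def __post_init__(self):
        self.I = as_tensor(self.I)
        if self.I.ndim == 1:
            self.I = Tensor(self.I.data[None]) if not self.I.requires_grad else self.I.reshape((1,) + self.I.shape)
        arr = self.I.data
        if arr.min() < -1e-6 or not np.allclose(arr.sum(axis=-1), 1.0, atol=1e-5):
            raise ValueError("level weights must be nonnegative and sum to 1")


def part_pooling(att: AttentionMaps, feat: FeatureMap) -> PartFeatureBank:
    """Attention-weighted spatial pooling: node i = sum_xy Fd_i(x,y) * X(x,y)."""
    maps = att.maps if isinstance(att, AttentionMaps) else as_tensor(att)
    if maps.ndim == 3:
        maps = Tensor(maps.data[None]) if not maps.requires_grad else maps.reshape((1,) + maps.shape)
    values = feat.values if isinstance(feat, FeatureMap) else as_tensor(feat)
    if values.ndim == 3:
        values = Tensor(values.data[None]) if not values.requires_grad else values.reshape((1,) + values.shape)
    if maps.shape[2:] != values.shape[2:]:
        raise ValueError("attention and feature maps must share spatial size")
    n, p = maps.shape[:2]
    d = values.shape[1]
    hw = maps.shape[2] * maps.shape[3]
    a = maps.reshape(n, p, hw)
    x = values.reshape(n, d, hw)
    nodes = a @ x.transpose(0, 2, 1)  # (N, P, D)
    level = att.level if isinstance(att, AttentionMaps) else 0
    return PartFeatureBank(nodes, level)


def adjacency(bank: PartFeatureBank, tau=None) -> Tensor:
    """A_tilde = cosine-similarity matrix of tau(nodes) plus the identity.

    A zero-norm transformed node yields similarity 0 against everything
    (including itself), never NaN.  Returns (N, P, P).
    """
    nodes = bank.nodes if isinstance(bank, PartFeatureBank) else as_tensor(bank)
    if nodes.ndim == 2:
        nodes = nodes.reshape((1,) + nodes.shape)
    t = tau(nodes) if tau is not None else nodes
    sq = (t * t).sum(axis=-1, keepdims=True)  # (N, P, 1)
    inv_norm = sq.clip_min(1e-24) ** -0.5
    unit = t * inv_norm
    a = unit @ unit.transpose(0, 2, 1)
    p = a.shape[1]
    return a + Tensor(np.eye(p, dtype=np.float32)[None])


def graph_propagate(bank, a_tilde, weight) -> Tensor:
    """One GCN step: ReLU(D^-1/2 A_tilde D^-1/2 K W).  Returns (N, P, Dh)."""
    k = bank.nodes if isinstance(bank, PartFeatureBank) else as_tensor(bank)
    if k.ndim == 2:
        k = k.reshape((1,) + k.shape)
    a = as_tensor(a_tilde)
    if a.ndim == 2:
        a = a.reshape((1,) + a.shape)
    w = as_tensor(weight)
    deg = a.sum(axis=-1, keepdims=True)  # (N, P, 1)
    if np.any(deg.data <= 0):
        raise ValueError("zero or negative row degree in A_tilde")
    dinv = deg ** -0.5
    norm_a = a * dinv * dinv.transpose(0, 2, 1)
    return (norm_a @ k @ w).relu()


class LevelAttention(nn.Module):
    """Adaptive per-level attention: eta_m = mean_i tanh(W_m g_mi + b_m)."""

    def __init__(self, dims: list[int], rng=None, shared=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.shared = shared
        n_heads = 1 if shared else len(dims)
        self.heads = [nn.Linear(dims[0] if shared else dims[i], 1, rng=rng) for i in range(n_heads)]

    def forward(self, g_levels: list[Tensor]) -> LevelWeights:
        etas = []
        for m, g in enumerate(g_levels):
            head = self.heads[0] if self.shared else self.heads[m]
            eta = head(g).tanh().mean(axis=(1, 2))  # (N,)
            etas.append(eta.reshape(-1, 1))
        stacked = concatenate(etas, axis=1)  # (N, L)
        return LevelWeights(stacked.softmax(axis=-1))


def level_attention(g_levels, params=None, seed: int = 0) -> LevelWeights:
    """Functional form of :class:`LevelAttention`.

    ``params`` may be a LevelAttention module or a list of (W, b) pairs with
    W of shape (D, 1); when omitted a fresh seeded module is used.
    """
    g_levels = [as_tensor(g) if not isinstance(g, Tensor) else g for g in g_levels]
    g_levels = [g.reshape((1,) + g.shape) if g.ndim == 2 else g for g in g_levels]
    if len(g_levels) < 1:
        raise ValueError("need at least one level")
    if isinstance(params, LevelAttention):
        return params(g_levels)
    if params is None:
        module = LevelAttention([g.shape[2] for g in g_levels], rng=np.random.default_rng(seed))
        return module(g_levels)
    etas = []
    for g, (w, b) in zip(g_levels, params):
        w, b = as_tensor(w), as_tensor(b)
        eta = (g @ w + b).tanh().mean(axis=(1, 2)).reshape(-1, 1)
        etas.append(eta)
    return LevelWeights(concatenate(etas, axis=1).softmax(axis=-1))


def fused_score(g_levels, weights: LevelWeights, classifier_heads) -> Tensor:
    """Convex mixture of per-level class distributions.

    Each head maps the node-mean of its level's embedding to class logits;
    the softmaxed logits are combined with the level weights.  Returns
    (N, K) probabilities summing to 1.
    """
    g_levels = [as_tensor(g) if not isinstance(g, Tensor) else g for g in g_levels]
    g_levels = [g.reshape((1,) + g.shape) if g.ndim == 2 else g for g in g_levels]
    if len(classifier_heads) != len(g_levels):
        raise ValueError("one classifier head per level is required")
    iw = weights.I if isinstance(weights, LevelWeights) else LevelWeights(weights).I
    if iw.shape[-1] != len(g_levels):
        raise ValueError("level-weight count must match level count")
    mix = None
    for m, (g, head) in enumerate(zip(g_levels, classifier_heads)):
        pooled = g.mean(axis=1)  # (N, D)
        logits = head(pooled) if callable(head) else pooled @ as_tensor(head[0]) + as_tensor(head[1])
        probs = logits.softmax(axis=-1)
        term = probs * iw[:, m : m + 1]
        mix = term if mix is None else mix + term
    return mix
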