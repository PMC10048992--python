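"""GPA-Net classifier assembly: CSP backbone + CTA pyramid + graph embedding.

Ablation variants are expressed through two switches:

===========  =========  =========================================================
use_cta      use_gfe    classifier path
===========  =========  =========================================================
False        False      backbone + global average pool + linear head
True         False      CTA part pooling, per-level heads, equal-weight mixture
False        True       grid nodes per stage -> graph layers -> adaptive fusion
True         True       full model (attention nodes -> graph -> adaptive fusion)
===========  =========  =========================================================
"""

from __future__ import annotations

import numpy as np

from . import nn
from .attention import CTAModule
from .autograd import Tensor
from .backbone import CSPBackbone, DEFAULT_STAGES, FeatureMap
from .graphs import LevelAttention, adjacency, fused_score, graph_propagate, part_pooling
from .losses import LOG_FLOOR

__all__ = ["GPANet", "classification_loss", "VARIANTS", "build_variant"]

VARIANTS = {
    "backbone": dict(use_cta=False, use_gfe=False),
    "backbone+cta": dict(use_cta=True, use_gfe=False),
    "backbone+gfe": dict(use_cta=False, use_gfe=True),
    "full": dict(use_cta=True, use_gfe=True),
}


def _pool_to_grid(values: Tensor, grid: int) -> Tensor:
    """(N, C, H, W) -> (N, grid*grid, C) node bank via average pooling."""
    n, c, h, w = values.shape
    gh, gw = min(grid, h), min(grid, w)
    pooled = values.reshape(n, c, gh, h // gh, gw, w // gw).mean(axis=(3, 5))
    return pooled.reshape(n, c, gh * gw).transpose(0, 2, 1)


class GPANet(nn.Module):
    def __init__(self, n_classes: int, stage_configs=DEFAULT_STAGES, use_cta=True,
                 use_gfe=True, node_cap=16, graph_dim=24, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.use_cta = use_cta
        self.use_gfe = use_gfe
        self.node_cap = node_cap
        self.backbone = CSPBackbone(stage_configs, rng=rng)
        stage_ch = {i + 1: cfg.out_channels for i, cfg in enumerate(self.backbone.configs)}
        self.level_stages = [4, 2, 3, 4]  # G0 (trunk) + pyramid levels
        dims = [stage_ch[s] for s in self.level_stages]
        if use_cta:
            self.cta = CTAModule({k: stage_ch[k] for k in (2, 3, 4)}, rng=rng)
        if use_gfe:
            self.taus = [nn.Linear(d, graph_dim, rng=rng) for d in dims]
            self.graph_ws = [
                Tensor(rng.normal(0, np.sqrt(2.0 / d), size=(d, graph_dim)).astype(np.float32),
                       requires_grad=True)
                for d in dims
            ]
            self.level_att = LevelAttention([graph_dim] * len(dims), rng=rng)
            self.heads = [nn.Linear(graph_dim, n_classes, rng=rng) for _ in dims]
        elif use_cta:
            self.heads = [nn.Linear(stage_ch[k], n_classes, rng=rng) for k in (2, 3, 4)]
        else:
            self.head = nn.Linear(stage_ch[4], n_classes, rng=rng)

    # -- node banks --------------------------------------------------------
    def _attention_banks(self, stages: dict[int, FeatureMap]):
        pyramid = [stages[k] for k in (2, 3, 4)]
        banks = []
        for att, phi in self.cta(pyramid):
            bank = part_pooling(att, stages[att.level])
            banks.append(self._cap_nodes(bank.nodes, att))
        return banks  # levels 2, 3, 4

    def _cap_nodes(self, nodes: Tensor, att) -> Tensor:
        if nodes.shape[1] <= self.node_cap:
            return nodes
        # keep the most concentrated part maps (peak attention mass)
        peaks = att.maps.data.max(axis=(2, 3)).mean(axis=0)
        keep = np.sort(np.argsort(-peaks)[: self.node_cap])
        return nodes[:, keep, :]

    # -- forward -----------------------------------------------------------
    def forward(self, x) -> Tensor:
        """Class probabilities, (N, K)."""
        outputs = self.backbone(x)
        stages = {fm.stage_index: fm for fm in outputs}

        if not self.use_cta and not self.use_gfe:
            pooled = stages[4].values.mean(axis=(2, 3))
            return self.head(pooled).softmax(axis=-1)

        if self.use_cta and not self.use_gfe:
            banks = self._attention_banks(stages)
            mix = None
            for bank, head in zip(banks, self.heads):
                probs = head(bank.mean(axis=1)).softmax(axis=-1)
                mix = probs if mix is None else mix + probs
            return mix * (1.0 / len(banks))

        # graph paths: level 0 = stage-4 trunk grid nodes
        g0_nodes = _pool_to_grid(stages[4].values, 4)
        if self.use_cta:
            level_nodes = [g0_nodes] + self._attention_banks(stages)
        else:
            level_nodes = [g0_nodes] + [
                _pool_to_grid(stages[k].values, 4) for k in (2, 3, 4)
            ]
        g_levels = []
        for nodes, tau, w in zip(level_nodes, self.taus, self.graph_ws):
            a_tilde = adjacency(nodes, tau=lambda t, _m=tau: _m(t).relu())
            g_levels.append(graph_propagate(nodes, a_tilde, w))
        weights = self.level_att(g_levels)
        return fused_score(g_levels, weights, self.heads)

    def predict(self, x) -> np.ndarray:
        return np.argmax(self.forward(x).data, axis=-1)


def classification_loss(probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean label-smoothed cross entropy; ``targets`` is (N, K) smoothed rows."""
    t = Tensor(np.asarray(targets, dtype=np.float32))
    logp = probs.clip_min(LOG_FLOOR).log()
    return -(t * logp).sum(axis=-1).mean()


def build_variant(name: str, n_classes: int, seed: int = 0, **kwargs) -> GPANet:
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    return GPANet(n_classes, seed=seed, **VARIANTS[name], **kwargs)
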