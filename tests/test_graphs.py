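import numpy as np
import pytest

from gpanet.attention import AttentionMaps
from gpanet.autograd import Tensor
from gpanet.backbone import FeatureMap
from gpanet.graphs import (LevelAttention, LevelWeights, PartFeatureBank,
                           adjacency, fused_score, graph_propagate,
                           level_attention, part_pooling)


def _softmax(v, axis=-1):
    e = np.exp(v - v.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


class TestPartPooling:
    def test_uniform_attention_is_global_average(self, rng):
        feat = FeatureMap(rng.normal(size=(1, 3, 2, 2)).astype(np.float32), 2)
        att = AttentionMaps(np.full((1, 2, 2, 2), 0.25, dtype=np.float32), 2)
        bank = part_pooling(att, feat)
        expected = feat.values.data[0].mean(axis=(1, 2))
        for node in bank.nodes.data[0]:
            np.testing.assert_allclose(node, expected, atol=1e-6)

    def test_single_hot_attention_picks_pixel(self, rng):
        feat = FeatureMap(rng.normal(size=(1, 4, 3, 3)).astype(np.float32), 2)
        maps = np.zeros((1, 1, 3, 3), dtype=np.float32)
        maps[0, 0, 2, 1] = 1.0
        bank = part_pooling(AttentionMaps(maps, 2), feat)
        np.testing.assert_allclose(bank.nodes.data[0, 0], feat.values.data[0, :, 2, 1], atol=1e-6)

    def test_brute_force_weighted_sum(self, rng):
        att_arr = _softmax(rng.normal(size=(1, 3, 4)).astype(np.float32)).reshape(1, 3, 2, 2)
        feat_arr = rng.normal(size=(1, 5, 2, 2)).astype(np.float32)
        bank = part_pooling(AttentionMaps(att_arr, 2), Tensor(feat_arr))
        for p in range(3):
            for d in range(5):
                acc = 0.0
                for y in range(2):
                    for x in range(2):
                        acc += att_arr[0, p, y, x] * feat_arr[0, d, y, x]
                assert bank.nodes.data[0, p, d] == pytest.approx(acc, abs=1e-5)

    def test_size_mismatch_rejected(self, rng):
        att = AttentionMaps(np.full((1, 2, 2, 2), 0.25, dtype=np.float32), 2)
        with pytest.raises(ValueError):
            part_pooling(att, Tensor(rng.normal(size=(1, 3, 4, 4)).astype(np.float32)))


class TestAdjacency:
    def test_identical_nodes_all_ones_plus_identity(self):
        nodes = np.tile(np.array([1.0, 2.0, 3.0], np.float32), (4, 1))
        a_tilde = adjacency(PartFeatureBank(nodes)).data[0]
        np.testing.assert_allclose(a_tilde, np.ones((4, 4)) + np.eye(4), atol=1e-5)

    def test_orthogonal_nodes_give_2I(self):
        nodes = np.eye(3, dtype=np.float32) * 5.0
        a_tilde = adjacency(PartFeatureBank(nodes)).data[0]
        np.testing.assert_allclose(a_tilde, 2 * np.eye(3), atol=1e-6)

    def test_brute_force_cosine(self, rng):
        nodes = rng.normal(size=(3, 4)).astype(np.float32)
        a_tilde = adjacency(PartFeatureBank(nodes)).data[0]
        for i in range(3):
            for j in range(3):
                num = sum(nodes[i, d] * nodes[j, d] for d in range(4))
                den = np.sqrt(sum(nodes[i, d] ** 2 for d in range(4))) * np.sqrt(
                    sum(nodes[j, d] ** 2 for d in range(4))
                )
                expected = num / den + (1.0 if i == j else 0.0)
                assert a_tilde[i, j] == pytest.approx(expected, abs=1e-5)

    def test_zero_norm_node_never_nan(self):
        nodes = np.array([[1.0, 0.0], [0.0, 0.0]], np.float32)
        a_tilde = adjacency(PartFeatureBank(nodes)).data[0]
        assert np.all(np.isfinite(a_tilde))
        assert a_tilde[0, 1] == 0.0 and a_tilde[1, 0] == 0.0
        assert a_tilde[1, 1] == 1.0  # only the self loop remains

    def test_symmetric_diag2_bounded(self, rng):
        nodes = rng.normal(size=(5, 3)).astype(np.float32)
        a_tilde = adjacency(PartFeatureBank(nodes)).data[0]
        np.testing.assert_allclose(a_tilde, a_tilde.T, atol=1e-5)
        np.testing.assert_allclose(np.diag(a_tilde), 2.0, atol=1e-5)
        off = a_tilde - 2 * np.eye(5) * 0  # |A_ij| <= 1 off-diagonal
        mask = ~np.eye(5, dtype=bool)
        assert np.all(np.abs(off[mask]) <= 1 + 1e-5)


class TestGraphPropagate:
    def test_single_node_scalar_normalization_cancels(self, rng):
        k = rng.normal(size=(1, 3)).astype(np.float32)
        w = rng.normal(size=(3, 2)).astype(np.float32)
        a_tilde = np.array([[2.0]], np.float32)
        g = graph_propagate(PartFeatureBank(k), a_tilde, w).data[0]
        np.testing.assert_allclose(g, np.maximum(k @ w, 0.0), atol=1e-5)

    def test_identity_weight_2I_adjacency_inert(self, rng):
        k = np.abs(rng.normal(size=(3, 3))).astype(np.float32)
        g = graph_propagate(PartFeatureBank(k), 2 * np.eye(3, dtype=np.float32), np.eye(3, dtype=np.float32))
        np.testing.assert_allclose(g.data[0], k, atol=1e-5)

    def test_brute_force_oracle(self, rng):
        for n, d, dh in [(3, 4, 2), (5, 3, 4), (2, 2, 2)]:
            k = rng.normal(size=(n, d)).astype(np.float32)
            a_tilde = adjacency(PartFeatureBank(k)).data[0].astype(np.float64)
            w = rng.normal(size=(d, dh)).astype(np.float32)
            deg = a_tilde.sum(axis=1)
            expected = np.zeros((n, dh))
            for i in range(n):
                for out_d in range(dh):
                    acc = 0.0
                    for j in range(n):
                        norm = a_tilde[i, j] / np.sqrt(deg[i]) / np.sqrt(deg[j])
                        for dd in range(d):
                            acc += norm * k[j, dd] * w[dd, out_d]
                    expected[i, out_d] = max(acc, 0.0)
            got = graph_propagate(PartFeatureBank(k), Tensor(a_tilde.astype(np.float32)), w).data[0]
            np.testing.assert_allclose(got, expected, atol=1e-4)

    def test_zero_degree_rejected(self):
        k = np.ones((2, 2), np.float32)
        bad = np.zeros((2, 2), np.float32)
        with pytest.raises(ValueError, match="degree"):
            graph_propagate(PartFeatureBank(k), bad, np.eye(2, dtype=np.float32))


class TestLevelAttention:
    def test_single_level_weight_is_one(self, rng):
        g = rng.normal(size=(1, 4, 3)).astype(np.float32)
        lw = level_attention([Tensor(g)], seed=0)
        np.testing.assert_allclose(lw.I.data, [[1.0]], atol=1e-7)

    def test_identical_levels_shared_params_equal_weights(self, rng):
        g = Tensor(rng.normal(size=(2, 4, 3)).astype(np.float32))
        module = LevelAttention([3, 3, 3], rng=np.random.default_rng(1), shared=True)
        lw = module([g, g, g])
        np.testing.assert_allclose(lw.I.data, 1.0 / 3.0, atol=1e-6)

    def test_direct_evaluation_oracle(self, rng):
        gs = [rng.normal(size=(1, 3, 2)).astype(np.float32) for _ in range(3)]
        params = [(rng.normal(size=(2, 1)).astype(np.float32), rng.normal(size=1).astype(np.float32)) for _ in range(3)]
        lw = level_attention([Tensor(g) for g in gs], params=params)
        etas = [np.tanh(g[0] @ w + b).mean() for g, (w, b) in zip(gs, params)]
        expected = _softmax(np.array(etas, dtype=np.float64))
        np.testing.assert_allclose(lw.I.data[0], expected, atol=1e-5)

    def test_permutation_equivariance(self, rng):
        gs = [rng.normal(size=(1, 3, 2)).astype(np.float32) for _ in range(3)]
        params = [(rng.normal(size=(2, 1)).astype(np.float32), rng.normal(size=1).astype(np.float32)) for _ in range(3)]
        base = level_attention([Tensor(g) for g in gs], params=params).I.data[0]
        perm = [2, 0, 1]
        permuted = level_attention([Tensor(gs[p]) for p in perm], params=[params[p] for p in perm]).I.data[0]
        np.testing.assert_allclose(permuted, base[perm], atol=1e-6)

    def test_weights_sum_to_one(self, rng):
        gs = [Tensor(rng.normal(size=(3, 4, 2)).astype(np.float32)) for _ in range(4)]
        lw = level_attention(gs, seed=2)
        np.testing.assert_allclose(lw.I.data.sum(axis=1), 1.0, atol=1e-6)
        assert lw.I.data.min() >= 0


class TestFusedScore:
    @staticmethod
    def _head(w, b):
        return lambda pooled: pooled @ Tensor(w) + Tensor(b)

    def test_single_level_equals_its_softmax(self, rng):
        g = rng.normal(size=(1, 3, 4)).astype(np.float32)
        w = rng.normal(size=(4, 5)).astype(np.float32)
        b = np.zeros(5, np.float32)
        out = fused_score([Tensor(g)], LevelWeights(np.array([1.0], np.float32)), [self._head(w, b)])
        expected = _softmax(g[0].mean(axis=0) @ w)
        np.testing.assert_allclose(out.data[0], expected, atol=1e-5)

    def test_output_is_distribution(self, rng):
        gs = [Tensor(rng.normal(size=(2, 3, 4)).astype(np.float32)) for _ in range(3)]
        heads = [self._head(rng.normal(size=(4, 6)).astype(np.float32), rng.normal(size=6).astype(np.float32)) for _ in range(3)]
        weights = LevelWeights(_softmax(rng.normal(size=(2, 3))).astype(np.float32))
        out = fused_score(gs, weights, heads).data
        assert out.min() >= 0
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-5)

    def test_hand_mixture(self, rng):
        logits_a = np.array([[2.0, 0.0, 0.0]], np.float32)
        logits_b = np.array([[0.0, 1.0, 0.0]], np.float32)
        gs = [Tensor(logits_a[:, None, :]), Tensor(logits_b[:, None, :])]
        heads = [lambda p: p, lambda p: p]  # identity heads
        weights = LevelWeights(np.array([0.3, 0.7], np.float32))
        out = fused_score(gs, weights, heads).data[0]
        expected = 0.3 * _softmax(logits_a[0]) + 0.7 * _softmax(logits_b[0])
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_head_count_mismatch_rejected(self, rng):
        g = Tensor(rng.normal(size=(1, 2, 3)).astype(np.float32))
        with pytest.raises(ValueError):
            fused_score([g, g], LevelWeights(np.array([0.5, 0.5], np.float32)), [lambda p: p])


def test_level_weights_validation():
    with pytest.raises(ValueError):
        LevelWeights(np.array([0.5, 0.2], np.float32))
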