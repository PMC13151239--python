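"""The adaptive multi-order moment convolution layer."""

import numpy as np
import pytest

from mirmoment.autodiff import Tensor
from mirmoment.layer import (
    AdaptiveMomentConv,
    LayerConfig,
    compute_raw_moments,
    dynamic_threshold,
    effective_weights,
    gate_orders,
    sample_order_weights,
    stabilize_moments,
    topk_mask,
)

from conftest import random_normalized_graph


class TestRawMoments:
    def test_single_neighbor_powers(self):
        # node 0 has one neighbor (node 1) with weight 1 and h = (2, -1)
        adj = np.array([[0.0, 1.0], [0.0, 0.0]])
        H = np.array([[9.0, 9.0], [2.0, -1.0]])
        m = compute_raw_moments(H, adj, 3)
        np.testing.assert_allclose(m[0, 0], [2.0, -1.0])
        np.testing.assert_allclose(m[1, 0], [4.0, 1.0])
        np.testing.assert_allclose(m[2, 0], [8.0, -1.0])

    def test_isolated_node_all_orders_zero(self):
        adj = np.zeros((2, 2))
        m = compute_raw_moments(np.ones((2, 3)), adj, 5)
        np.testing.assert_array_equal(m[:, :, :], 0.0)

    def test_uniform_weights_scalar_feature(self):
        # neighbors with values {1, 3}, weights 0.5 each
        adj = np.array([[0.0, 0.5, 0.5], [0, 0, 0], [0, 0, 0]])
        H = np.array([[0.0], [1.0], [3.0]])
        m = compute_raw_moments(H, adj, 2)
        assert m[0, 0, 0] == pytest.approx(2.0)
        assert m[1, 0, 0] == pytest.approx(5.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(10):
            n, d = 8, 4
            _, adj = random_normalized_graph(rng, n)
            H = rng.normal(0, 2, (n, d))
            got = compute_raw_moments(H, adj, 10)
            exp = np.zeros((10, n, d))
            for k in range(1, 11):
                for i in range(n):
                    for j in range(n):
                        exp[k - 1, i] += adj[i, j] * H[j] ** k
            np.testing.assert_allclose(got, exp, atol=1e-10)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            compute_raw_moments(np.ones((2, 2)), np.eye(2), 0)


class TestStabilizedMoments:
    def test_order1_bit_identical_to_mean_aggregation(self, rng):
        _, adj = random_normalized_graph(rng, 7)
        H = rng.normal(0, 1, (7, 3))
        st = stabilize_moments(H, adj, 6)
        assert np.array_equal(st[0], adj @ H)

    def test_constant_neighborhood_vanishes_beyond_order_one(self):
        adj = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        st = stabilize_moments(np.full((3, 2), 2.0), adj, 10)
        np.testing.assert_array_equal(st[1:], 0.0)

    def test_uniform_pair_variance(self):
        adj = np.array([[0.0, 0.5, 0.5], [0, 0, 0], [0, 0, 0]])
        H = np.array([[0.0], [1.0], [3.0]])
        st = stabilize_moments(H, adj, 2)
        assert st[1, 0, 0] == pytest.approx(1.0)  # 5 - 2^2

    def test_symmetric_neighborhood_odd_moment_zero(self):
        adj = np.array([[0.0, 0.5, 0.5], [0, 0, 0], [0, 0, 0]])
        H = np.array([[0.0], [-1.5], [1.5]])
        st = stabilize_moments(H, adj, 3)
        assert st[2, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_oracle_on_resolvable_entries(self, rng):
        """Orders >= 3 agree with the per-neighbor formula wherever the
        centered sum is resolvable above the binomial round-off floor."""
        checked = 0
        for _ in range(20):
            n, d, M = 8, 4, 10
            _, adj = random_normalized_graph(rng, n)
            H = rng.normal(0, 1.5, (n, d))
            st = stabilize_moments(H, adj, M)
            mu = adj @ H
            var = np.maximum(adj @ H**2 - mu**2, 0)
            s = np.sqrt(var + 1e-6)
            for k in range(3, M + 1):
                direct = (
                    adj[:, :, None] * ((H[None] - mu[:, None]) / s[:, None]) ** k
                ).sum(axis=1)
                clipped = np.clip(direct, -10, 10)
                oracle = np.sign(clipped) * np.log1p(np.abs(clipped))
                # resolvability: centered sum above the round-off floor of the
                # raw-moment expansion
                mag = (
                    adj[:, :, None] * (np.abs(H[None]) + np.abs(mu[:, None])) ** k
                ).sum(axis=1)
                resolvable = np.abs(direct * s**k) > 1e-12 * mag
                np.testing.assert_allclose(
                    st[k - 1][resolvable], oracle[resolvable], atol=1e-4
                )
                checked += resolvable.sum()
        assert checked > 1000  # the mask must not trivialize the comparison

    def test_finite_for_large_features_at_all_orders(self, rng):
        _, adj = random_normalized_graph(rng, 8)
        H = rng.uniform(-1e3, 1e3, (8, 4))
        st = stabilize_moments(H, adj, 10)
        assert np.isfinite(st).all()
        assert np.abs(st[2:]).max() <= np.log1p(10.0) + 1e-12


class TestOrderSelection:
    def test_uniform_logits_give_uniform_weights(self):
        w = sample_order_weights(np.zeros(10), mode="infer")
        np.testing.assert_allclose(w, 0.1, atol=1e-12)

    def test_softmax_closed_form(self):
        w = sample_order_weights(np.array([np.log(2.0), 0.0]), mode="infer")
        np.testing.assert_allclose(w, [2 / 3, 1 / 3], atol=1e-12)

    def test_gumbel_low_temperature_approaches_one_hot(self):
        logits = np.array([0.5, -0.2, 0.1, 0.8])
        w_soft = sample_order_weights(logits, "train", gumbel_temperature=1.0, seed=9)
        w_hard = sample_order_weights(logits, "train", gumbel_temperature=1e-3, seed=9)
        assert np.argmax(w_hard) == np.argmax(w_soft)  # same perturbed argmax
        assert w_hard.max() > 0.999
        assert w_soft.max() < 0.999

    @pytest.mark.parametrize("mode", ["train", "infer"])
    def test_weights_sum_to_one(self, mode, rng):
        w = sample_order_weights(rng.normal(size=8), mode, seed=1)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()

    def test_invalid_temperature_rejected(self):
        with pytest.raises(ValueError):
            sample_order_weights(np.zeros(3), "train", gumbel_temperature=0.0)


class TestDynamicThreshold:
    def test_zero_network_gives_half_scale(self):
        H = np.zeros((5, 4))
        tau = dynamic_threshold(H, np.zeros((4, 8)), np.zeros(8), np.zeros(8), 0.0, 0.2)
        assert tau == pytest.approx(0.1)  # sigmoid(0) * 2/M_max at M_max 10

    def test_range_and_permutation_invariance(self, rng):
        H = rng.normal(size=(6, 4))
        w1, b1 = rng.normal(size=(4, 8)), rng.normal(size=8)
        w2, b2 = rng.normal(size=8), 0.3
        tau = dynamic_threshold(H, w1, b1, w2, b2, 0.2)
        assert 0.0 < tau < 0.2
        perm = rng.permutation(6)
        assert dynamic_threshold(H[perm], w1, b1, w2, b2, 0.2) == pytest.approx(tau)


class TestGating:
    def test_weight_at_threshold_gives_half(self):
        assert gate_orders(np.array([0.3]), 0.3, 0.1)[0] == pytest.approx(0.5)

    def test_one_temperature_unit_above_threshold(self):
        g = gate_orders(np.array([0.4]), 0.3, 0.1)[0]
        assert g == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-9)

    def test_hard_threshold_limit(self):
        g = gate_orders(np.array([0.31, 0.29]), 0.3, 1e-6)
        assert g[0] > 1 - 1e-9 and g[1] < 1e-9

    def test_monotone_in_weight(self):
        w = np.linspace(0, 1, 11)
        g = gate_orders(w, 0.5, 0.1)
        assert (np.diff(g) > 0).all()


class TestTopK:
    @pytest.mark.parametrize("k", range(1, 13))
    @pytest.mark.parametrize("m", range(1, 13))
    def test_mask_cardinality(self, k, m, rng):
        w = rng.random(m)
        assert topk_mask(w, k).sum() == min(k, m)

    def test_tie_breaks_to_lower_order(self):
        eff, mask = effective_weights(np.full(3, 0.5), np.array([0.3, 0.3, 0.4]), k=2)
        np.testing.assert_array_equal(mask, [1, 0, 1])

    def test_k_at_least_m_keeps_all_and_effective_equals_gates(self):
        g = np.array([0.2, 0.7, 0.9])
        eff, mask = effective_weights(g, np.array([0.1, 0.5, 0.4]), k=5)
        np.testing.assert_array_equal(mask, 1.0)
        np.testing.assert_array_equal(eff, g)

    def test_exactly_k_nonzero_effective_weights(self, rng):
        w = sample_order_weights(rng.normal(size=10), "infer")
        eff, mask = effective_weights(gate_orders(w, 0.1, 0.1), w, k=5)
        assert (eff > 0).sum() == 5
        np.testing.assert_array_equal(eff[mask == 0], 0.0)


def make_layer(dim=6, seed=0, **cfg_kw):
    cfg = LayerConfig(**cfg_kw)
    return AdaptiveMomentConv(dim, cfg, np.random.default_rng(seed)), cfg


class TestLayerForward:
    def test_attention_rows_sum_to_one_and_masked_orders_zero(self, rng):
        layer, cfg = make_layer(m_max=8, top_k=3)
        layer.order_logits.data = rng.normal(size=8)
        _, adj = random_normalized_graph(rng, 9)
        H = Tensor(rng.normal(size=(9, 6)))
        _, st = layer.forward(H, adj, mode="infer")
        np.testing.assert_allclose(st.attention.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(st.attention[:, st.topk_mask == 0], 0.0)

    def test_equal_scores_give_uniform_attention_over_retained(self, rng):
        layer, _ = make_layer(m_max=4, top_k=4)
        layer.attn_vec.data[:] = 0.0  # all scores identical
        _, adj = random_normalized_graph(rng, 6)
        _, st = layer.forward(Tensor(rng.normal(size=(6, 6))), adj, mode="infer")
        np.testing.assert_allclose(st.attention, 0.25, atol=1e-12)

    def test_one_masked_of_three_splits_evenly(self, rng):
        layer, _ = make_layer(m_max=3, top_k=2)
        layer.attn_vec.data[:] = 0.0
        layer.order_logits.data = np.array([1.0, 0.0, 2.0])  # mask drops order 2
        _, adj = random_normalized_graph(rng, 5)
        _, st = layer.forward(Tensor(rng.normal(size=(5, 6))), adj, mode="infer")
        np.testing.assert_allclose(st.attention[:, [0, 2]], 0.5, atol=1e-12)
        np.testing.assert_array_equal(st.attention[:, 1], 0.0)

    def test_zero_projection_reduces_to_residual_activation(self, rng):
        layer, _ = make_layer(m_max=5, top_k=3)
        layer.proj_w.data[:] = 0.0
        layer.proj_b.data[:] = 0.0
        _, adj = random_normalized_graph(rng, 6)
        H = rng.normal(size=(6, 6))
        out, _ = layer.forward(Tensor(H), adj, mode="infer")
        np.testing.assert_allclose(out.data, np.maximum(H, 0.0), atol=1e-12)

    def test_output_shape_matches_input(self, rng):
        layer, _ = make_layer()
        _, adj = random_normalized_graph(rng, 7)
        out, _ = layer.forward(Tensor(rng.normal(size=(7, 6))), adj, mode="infer")
        assert out.shape == (7, 6)

    def test_permutation_equivariance(self, rng):
        layer, _ = make_layer(m_max=6, top_k=3)
        layer.order_logits.data = rng.normal(size=6)
        _, adj = random_normalized_graph(rng, 8)
        H = rng.normal(size=(8, 6))
        out, _ = layer.forward(Tensor(H), adj, mode="infer")
        perm = rng.permutation(8)
        out_p, _ = layer.forward(
            Tensor(H[perm]), adj[np.ix_(perm, perm)], mode="infer"
        )
        np.testing.assert_allclose(out_p.data, out.data[perm], atol=1e-9)

    def test_gradient_reaches_order_logits(self, rng):
        layer, _ = make_layer(m_max=5, top_k=3)
        layer.order_logits.data = rng.normal(size=5)
        _, adj = random_normalized_graph(rng, 6)
        H = Tensor(rng.normal(size=(6, 6)))
        out, st = layer.forward(H, adj, mode="infer")
        (out * out).sum().backward()
        g = layer.order_logits.grad
        assert g is not None
        retained = st.topk_mask > 0
        assert np.abs(g[retained]).max() > 0.0
        # finite-difference check on the largest-gradient retained order
        k = int(np.argmax(np.abs(g) * retained))
        eps = 1e-5
        vals = []
        for sign in (+1, -1):
            layer.order_logits.data[k] += sign * eps
            o, _ = layer.forward(H, adj, mode="infer")
            vals.append(float((o * o).sum().data))
            layer.order_logits.data[k] -= sign * eps
        num = (vals[0] - vals[1]) / (2 * eps)
        assert num == pytest.approx(g[k], rel=1e-3, abs=1e-8)

    def test_hard_limit_selects_topk_of_softmax(self, rng):
        """With tiny gate temperature the layer reduces to a fixed order
        subset: gates are 0/1 and the retained set is the softmax Top-K.

        Order weights are placed well away from the threshold (tau = 0.1 by
        zero-initialized threshold net) so the hard limit is unambiguous.
        """
        layer, cfg = make_layer(m_max=10, top_k=5, gate_gamma=1e-4, gumbel_tau=1e-3)
        target_w = np.array([0.18] * 5 + [0.02] * 5)
        layer.order_logits.data = np.log(target_w)
        for p in (layer.thr_w1, layer.thr_b1, layer.thr_w2, layer.thr_b2):
            p.data[...] = 0.0
        _, adj = random_normalized_graph(rng, 8)
        _, st = layer.forward(Tensor(rng.normal(size=(8, 6))), adj, mode="infer")
        np.testing.assert_allclose(st.gates, [1.0] * 5 + [0.0] * 5, atol=1e-6)
        w = sample_order_weights(layer.order_logits.data, "infer")
        np.testing.assert_array_equal(st.topk_mask, topk_mask(w, 5))
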