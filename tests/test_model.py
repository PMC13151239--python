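"""Network forward, pair scoring, loss, metrics, training and ranking."""

import numpy as np
import pytest

from mirmoment.model import (
    CVResult,
    ModelConfig,
    MomentNet,
    bce_loss,
    compute_metrics,
    rank_candidates,
    score_pairs,
)

from conftest import random_normalized_graph


class TestForward:
    def make(self, n_d=3, n_m=4, hidden=8, **kw):
        cfg = ModelConfig(hidden_dim=hidden, m_max=4, top_k=2, seed=5, **kw)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(n_d + n_m, 10))
        _, adj = random_normalized_graph(rng, n_d + n_m)
        return MomentNet(10, n_d, cfg), X, adj

    def test_split_shapes(self):
        model, X, adj = self.make()
        h, states = model.forward(X, adj)
        hd, hm = model.split_embeddings(h.data)
        assert hd.shape == (3, 8) and hm.shape == (4, 8)
        assert len(states) == 2

    def test_inference_is_deterministic(self):
        model, X, adj = self.make()
        h1, _ = model.forward(X, adj, mode="infer")
        h2, _ = model.forward(X, adj, mode="infer")
        np.testing.assert_array_equal(h1.data, h2.data)

    def test_dropout_only_in_training_mode(self):
        model, X, adj = self.make()
        rng = np.random.default_rng(0)
        h_train1, _ = model.forward(X, adj, mode="train", rng=rng)
        h_infer, _ = model.forward(X, adj, mode="infer")
        # training forward differs from the deterministic inference path
        assert not np.allclose(h_train1.data, h_infer.data)


class TestScorePairs:
    def test_zero_scorer_gives_half(self, rng):
        hd, hm = rng.normal(size=(3, 4)), rng.normal(size=(5, 4))
        pairs = np.array([[0, 0], [2, 4]])
        p = score_pairs(hd, hm, pairs, np.zeros(8), 0.0)
        np.testing.assert_allclose(p, 0.5)

    def test_bias_log3_gives_three_quarters(self, rng):
        hd, hm = rng.normal(size=(2, 4)), rng.normal(size=(2, 4))
        p = score_pairs(hd, hm, np.array([[0, 1]]), np.zeros(8), np.log(3.0))
        assert p[0] == pytest.approx(0.75, abs=1e-12)

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        hd, hm = rng.normal(size=(4, 6)), rng.normal(size=(4, 6))
        pairs = np.stack(np.meshgrid(np.arange(4), np.arange(4))).reshape(2, -1).T
        p = score_pairs(hd, hm, pairs, rng.normal(size=12), 1.0)
        assert ((p > 0) & (p < 1)).all()

    def test_out_of_range_pair_rejected(self, rng):
        hd, hm = rng.normal(size=(2, 4)), rng.normal(size=(2, 4))
        with pytest.raises(IndexError):
            score_pairs(hd, hm, np.array([[0, 5]]), np.zeros(8), 0.0)


class TestBceLoss:
    def test_uninformative_prediction_is_log_two(self):
        y = np.array([1.0, 0.0, 1.0])
        assert bce_loss(np.full(3, 0.5), y) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_hand_computed_case(self):
        loss = bce_loss(np.array([0.9, 0.1]), np.array([1.0, 0.0]))
        assert loss == pytest.approx(-np.log(0.9), abs=1e-12)

    def test_perfect_clamped_prediction_is_near_zero(self):
        y = np.array([1.0, 0.0])
        assert bce_loss(y, y) < 1e-6

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.array([0.5]), np.array([1.0, 0.0]))


class TestMetrics:
    def test_confusion_formulas_hand_case(self):
        # TP=3, TN=4, FP=1, FN=2 at threshold 0.5
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.1, 0.2, 0.6, 0.3, 0.2, 0.1, 0.4])
        m = compute_metrics(s, y)
        assert m["accuracy"] == pytest.approx(0.7, abs=1e-12)
        assert m["precision"] == pytest.approx(0.75, abs=1e-12)
        assert m["f1"] == pytest.approx(6 / 9, abs=1e-12)

    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        m = compute_metrics(s, y)
        assert m["auc"] == 1.0 and m["aupr"] == 1.0

    def test_random_scores_near_half_auc(self):
        rng = np.random.default_rng(123)
        y = rng.integers(0, 2, size=10_000)
        s = rng.random(10_000)
        assert compute_metrics(s, y)["auc"] == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="one class"):
            compute_metrics(np.array([0.5, 0.6]), np.array([1, 1]))

    def test_auc_matches_all_pairs_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(20, 200))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # coarse grid forces ties
            auc = compute_metrics(s, y)["auc"]
            pos, neg = s[y == 1], s[y == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert auc == pytest.approx(oracle, abs=1e-12)


class TestTraining:
    def test_holdout_never_enters_training_loss(self, small_cv):
        result = small_cv["result"]
        # reconstruct: per fold, test pairs must be disjoint from train pairs
        seen = []
        for f in result.folds:
            seen.append({tuple(p) for p in f.test_pairs.tolist()})
        for a in range(len(seen)):
            for b in range(a + 1, len(seen)):
                assert not (seen[a] & seen[b])

    def test_fold_metrics_lie_in_unit_interval(self, small_cv):
        for f in small_cv["result"].folds:
            for v in f.metrics.values():
                assert 0.0 <= v <= 1.0

    def test_training_loss_finite_and_improving(self, small_cv):
        deltas = []
        for f in small_cv["result"].folds:
            assert np.isfinite(f.train_losses).all()
            deltas.append(f.train_losses[-1] - f.train_losses[0])
        # the objective is stochastic (Gumbel sampling, dropout): require
        # improvement on average across folds rather than per epoch
        assert np.mean(deltas) < 0

    def test_metric_aggregation_matches_hand_mean_sd(self, small_cv):
        result = small_cv["result"]
        table = result.metric_table()
        aucs = np.array([f.metrics["auc"] for f in result.folds])
        assert table["auc"][0] == pytest.approx(aucs.mean(), abs=1e-12)
        assert table["auc"][1] == pytest.approx(aucs.std(), abs=1e-12)

    def test_divergence_aborts_with_diagnostics(self, small_cv):
        from mirmoment.graph import make_folds, sample_negatives
        from mirmoment.model import train_fold

        data = small_cv["data"]
        pos = data.assoc.pair_array()
        neg = sample_negatives(data.assoc, len(pos), seed=0)
        part = make_folds(pos, neg, k=5, seed=0)
        X = np.random.default_rng(0).normal(size=(60, 12))
        X[0, 0] = np.inf  # poisoned input must abort, not emit NaN metrics
        adj = np.eye(60)
        cfg = ModelConfig(lr=1e-3, epochs=5, seed=0, hidden_dim=8, m_max=4, top_k=2)
        with pytest.raises(RuntimeError, match="diverged"):
            train_fold(part, 0, X, adj, cfg, 30)


class TestRanking:
    def test_scores_non_increasing_and_full_when_topn_large(self, rng):
        hd, hm = rng.normal(size=(3, 4)), rng.normal(size=(7, 4))
        ranked = rank_candidates(hd, hm, 1, rng.normal(size=8), 0.0, top_n=100)
        assert len(ranked) == 7
        scores = [s for _, s in ranked]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_default_top_n_is_fifty(self, rng):
        hd, hm = rng.normal(size=(2, 4)), rng.normal(size=(60, 4))
        ranked = rank_candidates(hd, hm, 0, rng.normal(size=8), 0.0)
        assert len(ranked) == 50

    def test_ties_break_to_lower_mirna_index(self, rng):
        hd = np.zeros((1, 4))
        hm = np.zeros((5, 4))  # all scores identical
        ranked = rank_candidates(hd, hm, 0, rng.normal(size=8), 0.0, top_n=5)
        assert [j for j, _ in ranked] == [0, 1, 2, 3, 4]

    def test_unknown_disease_rejected(self, rng):
        with pytest.raises(IndexError):
            rank_candidates(np.zeros((2, 4)), np.zeros((3, 4)), 9, np.zeros(8), 0.0)
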