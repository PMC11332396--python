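"""Gated-attention MIL: exact gradients, attention invariants, training rules."""

import numpy as np
import pytest

from milfusion.evaluation import auc
from milfusion.mil import (
    AttentionOutput, EarlyStopping, MILConfig, MILModel, attention_weights,
    bag_forward, bag_loss_and_grads, instance_loss, load_model,
    normalize_attention, predict_wsi_score, save_model, train_mil,
)
from milfusion.synthetic import PatchBag


def make_bag(X, case_id="b"):
    X = np.asarray(X, dtype=np.float32)
    n = X.shape[0]
    coords = np.stack([np.arange(n), np.zeros(n, dtype=int)], axis=1).astype(np.int32)
    return PatchBag(case_id=case_id, features=X, grid_coords=coords)


@pytest.fixture
def small_model():
    return MILModel(MILConfig(feature_dim=6, hidden_dim=8, attention_dim=5,
                              instance_k=3, seed=2))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        cfg = MILConfig(feature_dim=5, hidden_dim=7, attention_dim=4, instance_k=3)
        m = MILModel(cfg)
        # move the (zero-initialized) classifiers off zero so their
        # gradients are informative
        m.params["Wc"] = rng.standard_normal((7, 2)) * 0.3
        m.params["bc"] = rng.standard_normal(2) * 0.1
        m.params["Wi"] = rng.standard_normal((7, 2)) * 0.3
        m.params["bi"] = rng.standard_normal(2) * 0.1
        X = rng.standard_normal((12, 5))
        _, grads = bag_loss_and_grads(m.params, X, 1, 0.7, 0.3, 3)
        eps = 1e-6
        for key, value in m.params.items():
            numeric = np.zeros_like(value)
            it = np.nditer(value, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                value[i] += eps
                lp, _ = bag_loss_and_grads(m.params, X, 1, 0.7, 0.3, 3)
                value[i] -= 2 * eps
                lm, _ = bag_loss_and_grads(m.params, X, 1, 0.7, 0.3, 3)
                value[i] += eps
                numeric[i] = (lp - lm) / (2 * eps)
            assert np.abs(numeric - grads[key]).max() < 1e-6, key


class TestDropout:
    def test_gradients_exact_under_fixed_mask(self):
        rng = np.random.default_rng(7)
        cfg = MILConfig(feature_dim=4, hidden_dim=6, attention_dim=3, instance_k=2)
        m = MILModel(cfg)
        m.params["Wc"] = rng.standard_normal((6, 2)) * 0.3
        m.params["Wi"] = rng.standard_normal((6, 2)) * 0.3
        X = rng.standard_normal((8, 4))
        mask = (rng.random((8, 6)) < 0.5) / 0.5
        _, grads = bag_loss_and_grads(m.params, X, 0, 0.7, 0.3, 2, drop_mask=mask)
        eps = 1e-6
        for key in ("Wp", "Wv", "w", "Wc"):
            value = m.params[key]
            it = np.nditer(value, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                value[i] += eps
                lp, _ = bag_loss_and_grads(m.params, X, 0, 0.7, 0.3, 2, drop_mask=mask)
                value[i] -= 2 * eps
                lm, _ = bag_loss_and_grads(m.params, X, 0, 0.7, 0.3, 2, drop_mask=mask)
                value[i] += eps
                assert (lp - lm) / (2 * eps) == pytest.approx(grads[key][i], abs=1e-6)

    def test_training_with_dropout_still_recovers(self, tiny_cohort, tiny_mil_config):
        from dataclasses import replace
        tr = tiny_cohort.subset("train")
        bags, labels = tr.bags(), tr.labels()
        cfg = replace(tiny_mil_config, dropout_rate=0.25)
        model, _ = train_mil(bags[8:], labels[8:], bags[:8], labels[:8], cfg)
        te = tiny_cohort.subset("test")
        scores = [predict_wsi_score(model, b) for b in te.bags()]
        assert auc(scores, te.labels()) >= 0.8


class TestAttention:
    def test_identical_patches_share_weight(self, small_model):
        bag = make_bag(np.tile(np.arange(6.0), (5, 1)))
        w = attention_weights(small_model, bag)
        assert np.allclose(w, 0.2)

    def test_weights_on_simplex(self, small_model):
        rng = np.random.default_rng(1)
        for _ in range(5):
            bag = make_bag(rng.standard_normal((rng.integers(1, 30), 6)))
            w = attention_weights(small_model, bag)
            assert (w >= 0).all()
            assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_permutation_equivariance(self, small_model):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((15, 6))
        perm = rng.permutation(15)
        w = attention_weights(small_model, make_bag(X))
        w_perm = attention_weights(small_model, make_bag(X[perm]))
        assert np.allclose(w[perm], w_perm)
        out = bag_forward(small_model, make_bag(X))
        out_perm = bag_forward(small_model, make_bag(X[perm]))
        assert out.wsi_score == pytest.approx(out_perm.wsi_score, abs=1e-12)

    def test_dimension_mismatch_raises(self, small_model):
        with pytest.raises(ValueError, match="feature dim"):
            attention_weights(small_model, make_bag(np.zeros((3, 4))))


class TestBagForward:
    def test_untrained_model_scores_half(self, small_model):
        # classifier weights initialize at zero -> logits are zero
        bag = make_bag(np.random.default_rng(0).standard_normal((10, 6)))
        assert bag_forward(small_model, bag).wsi_score == 0.5

    def test_duplicating_patches_preserves_score(self, small_model):
        rng = np.random.default_rng(3)
        small_model.params["Wc"] = rng.standard_normal((8, 2))
        X = rng.standard_normal((9, 6))
        s1 = predict_wsi_score(small_model, make_bag(X))
        s2 = predict_wsi_score(small_model, make_bag(np.vstack([X, X])))
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_single_patch_bag(self, small_model):
        out = bag_forward(small_model, make_bag(np.ones((1, 6))))
        assert out.raw_attention[0] == pytest.approx(1.0)
        assert out.normalized_score[0] == 1.0

    def test_empty_bag_raises(self, small_model):
        with pytest.raises(ValueError, match="empty"):
            bag_forward(small_model, make_bag(np.empty((0, 6))))


class TestNormalizeAttention:
    def test_rank_mapping(self):
        assert np.allclose(normalize_attention([0.1, 0.3, 0.6]), [0.0, 0.5, 1.0])

    def test_all_equal_scores_half(self):
        assert np.allclose(normalize_attention([0.2] * 7), 0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        raw = rng.random(20)
        assert np.allclose(normalize_attention(raw),
                           normalize_attention(np.exp(3 * raw)))


class TestInstanceLoss:
    def test_uniform_classifier_costs_ln2(self, small_model):
        # zero-initialized instance classifier is uniform over classes
        bag = make_bag(np.random.default_rng(5).standard_normal((10, 6)))
        assert instance_loss(small_model, bag, 1) == pytest.approx(np.log(2))

    def test_perfect_pseudo_label_match_costs_zero(self):
        # 1-d hidden space where attention and the instance classifier both
        # increase in the (positive) projected feature
        cfg = MILConfig(feature_dim=1, hidden_dim=1, attention_dim=1, instance_k=1)
        m = MILModel(cfg)
        m.params["Wp"] = np.array([[1.0]]); m.params["bp"] = np.zeros(1)
        m.params["Wv"] = np.array([[1.0]]); m.params["Wu"] = np.array([[5.0]])
        m.params["w"] = np.array([4.0])
        m.params["Wi"] = np.array([[-20.0, 20.0]])
        m.params["bi"] = np.array([30.0, -30.0])
        bag = make_bag(np.array([[1.0], [2.0]]))
        # top patch (x=2) pseudo-labelled 1, bottom (x=1) labelled 0;
        # classifier margins are +/-10 -> loss ~ softplus(-10)
        assert instance_loss(m, bag, 1) == pytest.approx(0.0, abs=1e-3)

    def test_k_reduced_on_small_bags(self, small_model):
        bag = make_bag(np.random.default_rng(6).standard_normal((3, 6)))
        assert instance_loss(small_model, bag, 1, k=8) >= 0.0


class TestEarlyStopping:
    def test_constant_loss_stops_after_patience(self):
        stopper = EarlyStopping(patience=20)
        stopped = None
        for epoch in range(1, 201):
            if stopper.update(epoch, 1.0):
                stopped = epoch
                break
        assert stopped == 21
        assert stopper.best_epoch == 1

    def test_strictly_decreasing_never_stops(self):
        stopper = EarlyStopping(patience=20)
        assert not any(stopper.update(e, 1.0 / e) for e in range(1, 201))
        assert stopper.best_epoch == 200

    def test_ties_do_not_reset_patience(self):
        stopper = EarlyStopping(patience=3)
        seq = [1.0, 0.5, 0.5, 0.5, 0.5]  # epoch 2 improves, 3-5 tie
        stops = [stopper.update(e, v) for e, v in enumerate(seq, start=1)]
        assert stops == [False, False, False, False, True]


class TestTraining:
    def test_recovers_planted_signal(self, trained_tiny, tiny_cohort):
        model, history = trained_tiny
        te = tiny_cohort.subset("test")
        scores = [predict_wsi_score(model, b) for b in te.bags()]
        assert auc(scores, te.labels()) >= 0.9
        assert history.best_epoch <= history.stopped_epoch

    def test_attention_finds_signal_patches(self, trained_tiny, tiny_cohort):
        model, _ = trained_tiny
        aurocs = []
        for bag, rec in tiny_cohort.subset("test").cases:
            if rec.recurrence and 0 < bag.signal_truth.sum() < bag.n_patches:
                out = bag_forward(model, bag)
                aurocs.append(auc(out.normalized_score, bag.signal_truth.astype(int)))
        assert np.mean(aurocs) >= 0.8

    def test_single_class_split_rejected(self, tiny_cohort, tiny_mil_config):
        bags = tiny_cohort.bags()[:6]
        with pytest.raises(ValueError, match="both classes"):
            train_mil(bags, [0] * 6, bags, [0] * 6, tiny_mil_config)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError, match="must equal 1"):
            MILConfig(bag_loss_weight=0.8, instance_loss_weight=0.3).validate()
        with pytest.raises(ValueError, match="patience"):
            MILConfig(patience=300, max_epochs=200).validate()


class TestCheckpoint:
    def test_round_trip_reproduces_predictions_exactly(self, trained_tiny,
                                                       tiny_cohort, tmp_path):
        model, _ = trained_tiny
        path = tmp_path / "model.npz"
        save_model(model, path)
        again = load_model(path)
        for bag in tiny_cohort.bags()[:5]:
            assert predict_wsi_score(model, bag) == predict_wsi_score(again, bag)
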