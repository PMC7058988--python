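"""Network forward pass, losses, analytic gradients, training, and saliency."""

import numpy as np
import pandas as pd
import pytest

from exp2sl.model import (
    EXP2SL,
    bpr_loss,
    encode,
    mse_loss,
    saliency_importance,
    score_pair,
    total_objective,
)


class TestEncode:
    def test_zero_layers_identity(self, rng):
        f = rng.normal(size=9)
        np.testing.assert_array_equal(encode(f, [], []), f)

    def test_relu_kills_negative_bias(self):
        w = np.zeros((3, 4))
        b = -np.ones(3)
        np.testing.assert_array_equal(encode(np.ones(4), [w], [b]), np.zeros(3))

    def test_hand_computed_toy_layer(self):
        w = np.array([[1.0, -1.0], [0.0, 2.0]])
        b = np.array([0.0, 1.0])
        np.testing.assert_allclose(encode(np.array([3.0, 1.0]), [w], [b]), [2.0, 3.0])

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            encode(np.ones(5), [np.zeros((3, 4))], [np.zeros(3)])


class TestScorePair:
    def test_zero_head_returns_bias(self, rng):
        h_i, h_j = rng.normal(size=(2, 6))
        assert score_pair(h_i, h_j, np.zeros(12), 3.25) == pytest.approx(3.25)

    def test_exact_symmetry_under_random_parameters(self, rng):
        for _ in range(25):
            h_i, h_j = rng.normal(size=(2, 8))
            w = rng.normal(size=16)
            b = rng.normal()
            assert score_pair(h_i, h_j, w, b) == score_pair(h_j, h_i, w, b)

    def test_hand_computed_example(self):
        # both concatenation orders average to 5
        s = score_pair(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                       np.array([1.0, 2.0, 3.0, 4.0]), 0.0)
        assert s == pytest.approx(5.0)


class TestLosses:
    def test_mse_zero_at_targets_and_unit_at_origin(self):
        assert mse_loss([1.0, -1.0], [1.0, -1.0]) == 0.0
        assert mse_loss([0.0], [1.0]) == 1.0
        assert mse_loss([0.5, -0.5], [1.0, -1.0]) == pytest.approx(0.5)

    def test_mse_empty_raises(self):
        with pytest.raises(ValueError):
            mse_loss([], [])

    def test_bpr_all_equal_scores(self):
        assert bpr_loss([0.0], [0.0], [0.0]) == pytest.approx(2 * np.log(2))

    def test_bpr_vanishes_at_perfect_margins(self):
        assert bpr_loss([1e4], [0.0], [-1e4]) == pytest.approx(0.0, abs=1e-10)

    def test_bpr_hand_computed_unit_margins(self):
        expected = -2 * np.log(1 / (1 + np.exp(-1)))
        assert bpr_loss([1.0], [0.0], [-1.0]) == pytest.approx(expected)
        assert expected == pytest.approx(0.6265, abs=1e-4)

    def test_bpr_decreasing_in_margins(self):
        base = bpr_loss([1.0], [0.0], [-1.0])
        assert bpr_loss([2.0], [0.0], [-1.0]) < base
        assert bpr_loss([1.0], [0.0], [-2.0]) < base

    def test_bpr_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bpr_loss([1.0, 2.0], [0.0], [-1.0])

    def test_total_objective_reduces_to_mse(self):
        assert total_objective([0.5], [1.0], [1], [0], [-1], 0.0, 0.0, 7.0) == \
            pytest.approx(0.25)

    def test_total_objective_monotone_in_l2(self):
        lo = total_objective([0.5], [1.0], [1], [0], [-1], 1.0, 0.0, 7.0)
        hi = total_objective([0.5], [1.0], [1], [0], [-1], 1.0, 0.1, 7.0)
        assert hi == pytest.approx(lo + 0.7)


def _tiny_problem(rng, n_genes=6, n_feat=7):
    genes = [f"g{i}" for i in range(n_genes)]
    sig = pd.DataFrame(rng.normal(size=(n_genes, n_feat)), index=genes)
    pairs = [("g0", "g1"), ("g2", "g3"), ("g0", "g2"), ("g4", "g5"), ("g1", "g4")]
    y = np.array([1, 1, -1, -1, -1])
    return sig, pairs, y


class TestObjectiveClosedForms:
    def test_zero_parameters_give_counting_loss(self, rng):
        """All scores are 0 at zero weights: MSE = |P u N|, BPR = 2K log 2."""
        sig, pairs, y = _tiny_problem(rng)
        model = EXP2SL(n_encoder_layers=0, lambda_bpr=16.0, lambda_l2=0.0)
        params = [np.zeros(2 * 7), np.zeros(())]
        lab_idx = np.array([[0, 1], [2, 3], [0, 2], [4, 5], [1, 4]])
        k = 2
        margins = [(lab_idx[:k], lab_idx[2:2 + k]), (lab_idx[2:2 + k], lab_idx[3:3 + k])]
        loss, _ = model._loss_and_grads(params, sig.to_numpy(), lab_idx,
                                        y.astype(float), margins)
        assert loss == pytest.approx(len(y) + 16.0 * 2 * k * np.log(2))

    def test_analytic_gradient_matches_finite_differences(self, rng):
        """Central finite differences on every parameter of a tiny E=1 model."""
        sig, pairs, y = _tiny_problem(rng)
        model = EXP2SL(n_encoder_layers=1, hidden_dim=4, lambda_bpr=8.0, lambda_l2=0.02)
        params = model._init_params(7, rng)
        feat = sig.to_numpy()
        lab_idx = np.array([[0, 1], [2, 3], [0, 2], [4, 5], [1, 4]])
        margins = [(np.array([[0, 1], [2, 3]]), np.array([[1, 2], [3, 4]])),
                   (np.array([[1, 2], [3, 4]]), np.array([[0, 2], [4, 5]]))]
        _, grads = model._loss_and_grads(params, feat, lab_idx, y.astype(float), margins)
        eps = 1e-6
        for p_i, p in enumerate(params):
            flat = p.reshape(-1) if p.ndim else p.reshape(1)
            gflat = grads[p_i].reshape(-1) if grads[p_i].ndim else grads[p_i].reshape(1)
            for j in range(flat.size):
                orig = flat[j]
                flat[j] = orig + eps
                up, _ = model._loss_and_grads(params, feat, lab_idx, y.astype(float), margins)
                flat[j] = orig - eps
                dn, _ = model._loss_and_grads(params, feat, lab_idx, y.astype(float), margins)
                flat[j] = orig
                fd = (up - dn) / (2 * eps)
                denom = max(abs(fd), abs(gflat[j]), 1e-8)
                assert abs(fd - gflat[j]) / denom < 1e-4


class TestTraining:
    HYPER = dict(n_encoder_layers=1, hidden_dim=16, lambda_bpr=16.0, lambda_l2=0.01,
                 n_epochs=150)

    def test_loss_decreases(self, small_fixture, small_labels):
        model = EXP2SL(**self.HYPER, random_state=0)
        model.fit_label_set(small_fixture["signatures"], small_labels)
        assert model.loss_curve_[-1] < model.loss_curve_[0]

    def test_same_seed_bitwise_identical(self, small_fixture, small_labels):
        fits = []
        for _ in range(2):
            m = EXP2SL(**{**self.HYPER, "n_epochs": 40}, random_state=3)
            m.fit_label_set(small_fixture["signatures"], small_labels)
            fits.append(m)
        a, b = fits
        assert np.array_equal(a.output_weight_, b.output_weight_)
        for wa, wb in zip(a.encoder_weights_, b.encoder_weights_):
            assert np.array_equal(wa, wb)

    def test_prediction_symmetry_and_hard_labels(self, small_fixture, small_labels):
        model = EXP2SL(**{**self.HYPER, "n_epochs": 40}, random_state=0)
        model.fit_label_set(small_fixture["signatures"], small_labels)
        pairs = small_labels.labeled_pairs()[:20]
        fwd = model.decision_function(pairs)
        rev = model.decision_function([(b, a) for a, b in pairs])
        np.testing.assert_array_equal(fwd, rev)
        assert set(model.predict(pairs)) <= {-1, 1}

    def test_empty_class_raises_with_set_name(self, rng):
        sig, pairs, y = _tiny_problem(rng)
        with pytest.raises(ValueError, match="P is empty"):
            EXP2SL().fit(sig, pairs, -np.ones(len(pairs)))
        with pytest.raises(ValueError, match="N is empty"):
            EXP2SL().fit(sig, pairs, np.ones(len(pairs)))

    def test_unknown_gene_raises(self, rng):
        sig, pairs, y = _tiny_problem(rng)
        model = EXP2SL(n_epochs=5).fit(sig, pairs, y)
        with pytest.raises(KeyError, match="nope"):
            model.decision_function([("g0", "nope")])

    def test_save_load_roundtrip(self, rng, tmp_path):
        sig, pairs, y = _tiny_problem(rng)
        model = EXP2SL(n_epochs=10, hidden_dim=4).fit(sig, pairs, y)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = EXP2SL.load(path)
        np.testing.assert_array_equal(model.decision_function(pairs),
                                      loaded.decision_function(pairs))

    def test_product_pairing_runs(self, rng):
        sig, pairs, y = _tiny_problem(rng)
        model = EXP2SL(n_epochs=5, hidden_dim=4, bpr_pairing="product")
        model.fit(sig, pairs, y)
        assert len(model.loss_curve_) == 5

    def test_sklearn_param_interface(self):
        model = EXP2SL(hidden_dim=32)
        assert model.get_params()["hidden_dim"] == 32
        model.set_params(lambda_bpr=4.0)
        assert model.lambda_bpr == 4.0


class TestSaliency:
    def _linear_model(self, n_feat, u, v, bias=0.0):
        model = EXP2SL(n_encoder_layers=0)
        model.encoder_weights_ = []
        model.encoder_biases_ = []
        model.output_weight_ = np.concatenate([u, v])
        model.output_bias_ = bias
        return model

    def test_linear_closed_form(self, rng):
        """For E = 0, importance_k = |P u N| * |u_k + v_k| exactly."""
        n_feat = 11
        u, v = rng.normal(size=(2, n_feat))
        sig = pd.DataFrame(rng.normal(size=(6, n_feat)),
                           index=[f"g{i}" for i in range(6)])
        pairs = [("g0", "g1"), ("g2", "g3"), ("g4", "g5"), ("g0", "g2")]
        imp = saliency_importance([self._linear_model(n_feat, u, v)], sig, pairs, k=5)
        np.testing.assert_allclose(imp.weights, len(pairs) * np.abs(u + v), atol=1e-10)

    def test_duplicated_models_double_weights_same_topk(self, rng):
        n_feat = 11
        u, v = rng.normal(size=(2, n_feat))
        sig = pd.DataFrame(rng.normal(size=(4, n_feat)),
                           index=[f"g{i}" for i in range(4)])
        pairs = [("g0", "g1"), ("g2", "g3")]
        m = self._linear_model(n_feat, u, v)
        one = saliency_importance([m], sig, pairs, k=4)
        two = saliency_importance([m, m], sig, pairs, k=4)
        np.testing.assert_allclose(two.weights, 2 * one.weights, atol=1e-12)
        np.testing.assert_array_equal(one.top_k, two.top_k)

    def test_zero_weight_dimension_has_zero_importance(self, rng):
        n_feat = 5
        u, v = rng.normal(size=(2, n_feat))
        u[2] = v[2] = 0.0
        sig = pd.DataFrame(rng.normal(size=(4, n_feat)),
                           index=[f"g{i}" for i in range(4)])
        sig.iloc[:, 2] = 0.0
        imp = saliency_importance([self._linear_model(n_feat, u, v)], sig,
                                  [("g0", "g1")], k=3)
        assert imp.weights[2] == 0.0

    def test_requires_pairs_and_models(self, rng):
        sig = pd.DataFrame(rng.normal(size=(2, 3)), index=["a", "b"])
        with pytest.raises(ValueError):
            saliency_importance([], sig, [("a", "b")])
        u, v = rng.normal(size=(2, 3))
        with pytest.raises(ValueError):
            saliency_importance([self._linear_model(3, u, v)], sig, [])
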