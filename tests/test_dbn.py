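"""RBM primitives, contrastive divergence, softmax head and fine-tuning."""

import numpy as np
import pytest

from eegmusic.dbn import (DBNClassifier, DBNModel, TrainConfig, cd_k_update,
                          finetune, load_model, loss_and_gradients, predict,
                          pretrain, rbm_conditional_hidden, rbm_init,
                          reconstruction_error, save_model,
                          softmax_probabilities)
from eegmusic.features import FeatureMatrix

from conftest import rbm_exact_loglik


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def toy_features(seed=0, n=60, separation=2.0, n_classes=2, dim=50):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        centre = np.zeros(dim)
        centre[c::n_classes] = separation * (1 if c % 2 == 0 else -1)
        X.append(rng.normal(0, 1, (n, dim)) + centre)
        y.extend([c] * n)
    return FeatureMatrix(X=np.vstack(X), y=np.array(y),
                         subject_ids=np.array(["s"] * n * n_classes, object),
                         column_names=[f"f{i}" for i in range(dim)])


class TestRBMPrimitives:
    def test_init_deterministic_shapes_and_zero_biases(self):
        a = rbm_init(6, 4, seed=3)
        b = rbm_init(6, 4, seed=3)
        np.testing.assert_array_equal(a.W, b.W)
        assert a.W.shape == (4, 6)
        assert not a.b_visible.any() and not a.b_hidden.any()

    def test_conditional_hidden_at_zero_weights(self):
        rbm = rbm_init(4, 3, seed=0)
        rbm.W[:] = 0.0
        np.testing.assert_allclose(rbm_conditional_hidden(rbm, np.ones(4)), 0.5)

    def test_conditional_hidden_hand_computed(self):
        rbm = rbm_init(2, 2, seed=0)
        rbm.W = np.array([[1.0, -1.0], [0.0, 2.0]])
        p = rbm_conditional_hidden(rbm, np.array([1.0, 1.0]))
        np.testing.assert_allclose(p, [sigmoid(0.0), sigmoid(2.0)])

    def test_conditional_hidden_monotone_in_positive_weight(self):
        rbm = rbm_init(3, 2, seed=1)
        rbm.W[0, 1] = 0.7
        v = np.array([0.2, 0.1, -0.3])
        base = rbm_conditional_hidden(rbm, v)[0]
        v[1] += 1.0
        assert rbm_conditional_hidden(rbm, v)[0] >= base


class TestContrastiveDivergence:
    data = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], float)

    def test_zero_learning_rate_is_identity(self):
        rbm = rbm_init(4, 3, seed=0)
        out = cd_k_update(rbm, self.data, k=1, lr=0.0, seed=1)
        np.testing.assert_array_equal(out.W, rbm.W)
        np.testing.assert_array_equal(out.b_hidden, rbm.b_hidden)

    def test_cd1_increases_exact_loglikelihood(self):
        """500 CD-1 epochs on an enumerable RBM raise the exact data
        log-likelihood computed via the brute-force partition function."""
        rbm = rbm_init(4, 3, "bernoulli", seed=0)
        ll0 = rbm_exact_loglik(rbm, self.data)
        rng = np.random.default_rng(42)
        for _ in range(500):
            rbm = cd_k_update(rbm, self.data, k=1, lr=0.1, seed=rng)
        assert rbm_exact_loglik(rbm, self.data) > ll0

    def test_cd1_direction_correlates_with_exact_gradient(self):
        """Average cosine between the CD-1 weight update and the exact
        likelihood gradient is positive at initialization (10 seeds)."""
        import itertools

        def exact_grad_w(rbm):
            ph = rbm_conditional_hidden(rbm, self.data)
            pos = ph.T @ self.data / len(self.data)
            states = [np.array(s, float)
                      for s in itertools.product([0, 1], repeat=4)]
            nfe = [float(v @ rbm.b_visible
                         + np.sum(np.logaddexp(0, rbm.W @ v + rbm.b_hidden)))
                   for v in states]
            p = np.exp(nfe - np.logaddexp.reduce(nfe))
            neg = sum(pi * np.outer(rbm_conditional_hidden(rbm, v), v)
                      for pi, v in zip(p, states))
            return pos - neg

        cosines = []
        for seed in range(10):
            rbm = rbm_init(4, 3, "bernoulli", seed=100 + seed)
            g = exact_grad_w(rbm)
            upd = cd_k_update(rbm, self.data, k=1, lr=0.1, seed=seed)
            d = (upd.W - rbm.W) / 0.1
            cosines.append(np.sum(d * g)
                           / (np.linalg.norm(d) * np.linalg.norm(g)))
        assert np.mean(cosines) > 0


class TestPretrain:
    def test_zero_epochs_returns_initialized_stack(self):
        fm = toy_features()
        cfg = TrainConfig(layer_sizes=(50, 30, 20), epochs_pretrain=0, seed=1)
        rbms = pretrain(fm, cfg)
        assert [r.W.shape for r in rbms] == [(30, 50), (20, 30)]
        assert not rbms[0].b_hidden.any()
        assert rbms[0].unit_type == "gaussian"
        assert rbms[1].unit_type == "bernoulli"

    @pytest.mark.parametrize("seed", range(10))
    def test_training_reduces_reconstruction_error(self, seed):
        fm = toy_features(seed=seed)
        X = (fm.X - fm.X.mean(0)) / fm.X.std(0)
        cfg0 = TrainConfig(layer_sizes=(50, 30), epochs_pretrain=0, seed=seed)
        cfg1 = TrainConfig(layer_sizes=(50, 30), epochs_pretrain=50,
                           lr_pretrain=0.01, seed=seed)
        e0 = reconstruction_error(pretrain(X, cfg0)[0], X)
        e1 = reconstruction_error(pretrain(X, cfg1)[0], X)
        assert e1 < e0

    def test_empty_training_set_rejected(self):
        fm = toy_features()
        with pytest.raises(ValueError):
            pretrain(fm, TrainConfig(seed=0),
                     train_mask=np.zeros(fm.n_epochs, bool))


class TestSoftmax:
    def test_zero_parameters_uniform(self):
        p = softmax_probabilities(np.zeros((5, 11)), np.ones(10))
        np.testing.assert_allclose(p, 0.2, atol=1e-12)

    def test_binary_case_reduces_to_logistic(self):
        rng = np.random.default_rng(0)
        theta = rng.normal(size=(2, 6))
        x = rng.normal(size=5)
        p = softmax_probabilities(theta, x)
        xb = np.append(x, 1.0)
        expected = sigmoid((theta[0] - theta[1]) @ xb)
        np.testing.assert_allclose(p[0], expected, atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        theta = rng.normal(size=(5, 11))
        x = rng.normal(size=10)
        p1 = softmax_probabilities(theta, x)
        p2 = softmax_probabilities(theta + 3.7, x)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_non_finite_rejected(self):
        theta = np.zeros((3, 4))
        theta[0, 0] = np.nan
        with pytest.raises(ValueError):
            softmax_probabilities(theta, np.ones(3))


def small_model(seed=0, dim=50):
    rng = np.random.default_rng(seed)
    cfg = TrainConfig(layer_sizes=(dim, 20, 10), epochs_pretrain=2, seed=seed)
    rbms = pretrain(rng.normal(size=(30, dim)), cfg)
    theta = 0.1 * rng.standard_normal((5, 11))
    return DBNModel(rbms=rbms, theta=theta, class_labels=list(range(5)))


class TestFinetune:
    def test_zero_learning_rate_constant_trace(self):
        fm = toy_features()
        model = small_model()
        cfg = TrainConfig(layer_sizes=(50, 20, 10), lr_finetune=0.0,
                          iterations_finetune=20, seed=0)
        _, trace = finetune(model, fm.X, fm.y, cfg)
        assert np.ptp(trace.mse_per_iteration) == 0.0

    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 50))
        y = rng.integers(0, 5, 10)
        model = small_model(seed=2)
        loss, g_theta, g_rbms = loss_and_gradients(model, X, y)
        eps = 1e-5

        def numeric(arr, idx):
            orig = arr[idx]
            arr[idx] = orig + eps
            lp, _, _ = loss_and_gradients(model, X, y)
            arr[idx] = orig - eps
            lm, _, _ = loss_and_gradients(model, X, y)
            arr[idx] = orig
            return (lp - lm) / (2 * eps)

        checks = [(model.theta, (3, 4), g_theta[3, 4]),
                  (model.rbms[0].W, (5, 7), g_rbms[0][0][5, 7]),
                  (model.rbms[1].W, (2, 3), g_rbms[1][0][2, 3]),
                  (model.rbms[0].b_hidden, (1,), g_rbms[0][1][1]),
                  (model.rbms[1].b_hidden, (4,), g_rbms[1][1][4])]
        for arr, idx, analytic in checks:
            num = numeric(arr, idx)
            assert abs(analytic - num) <= 1e-6 * max(abs(num), 1e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_separable_two_class_reaches_perfect_accuracy(self, seed):
        fm = toy_features(seed=seed, separation=2.0)
        mu, sd = fm.X.mean(0), fm.X.std(0)
        fm.X = (fm.X - mu) / sd
        cfg = TrainConfig(layer_sizes=(50, 40, 30), n_classes=2,
                          iterations_finetune=500, seed=seed)
        results = DBNClassifier(fm, cfg).fit()
        labels, _ = results.predict(fm.X)
        assert np.array_equal(labels, fm.y)


class TestPredict:
    def test_probability_rows_sum_to_one(self):
        model = small_model()
        X = np.random.default_rng(4).normal(size=(7, 50))
        _, P = predict(model, X)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        model = small_model()
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, 49)))

    def test_deterministic(self):
        model = small_model()
        X = np.random.default_rng(4).normal(size=(7, 50))
        a = predict(model, X)
        b = predict(model, X)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestReproducibilityAndSerialization:
    def test_fit_is_bit_reproducible(self):
        fm = toy_features(seed=5)
        cfg = TrainConfig(layer_sizes=(50, 20, 10), n_classes=2,
                          iterations_finetune=30, epochs_pretrain=3, seed=9)
        r1 = DBNClassifier(fm, cfg).fit()
        r2 = DBNClassifier(fm, cfg).fit()
        np.testing.assert_array_equal(r1.model.theta, r2.model.theta)
        for a, b in zip(r1.model.rbms, r2.model.rbms):
            np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(r1.trace.mse_per_iteration,
                                      r2.trace.mse_per_iteration)

    def test_save_load_roundtrip(self, tmp_path):
        model = small_model(seed=7)
        path = tmp_path / "model.json"
        save_model(model, path, config=TrainConfig(seed=7))
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.theta, model.theta)
        for a, b in zip(loaded.rbms, model.rbms):
            np.testing.assert_array_equal(a.W, b.W)
            assert a.unit_type == b.unit_type
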