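"""Network core: initialization, forward pass, analytic gradients, training."""

import numpy as np
import pytest

from sonoyeast.mlp import (
    CompactMLPClassifier,
    CompactMLPRegressor,
    NetworkWeights,
    forward,
    gradient,
    init_glorot,
    loss,
    train_lbfgs,
)

SIZES_REG = (9, 5, 3, 1)
SIZES_CLF = (9, 5, 3, 3)


def _rand_net(sizes, seed=0):
    return init_glorot(sizes, np.random.default_rng(seed))


def _finite_difference(net, X, y, l2, task, h=1e-6):
    sizes = net.layer_sizes
    flat = net.pack()
    grad = np.empty_like(flat)
    for k in range(flat.size):
        plus, minus = flat.copy(), flat.copy()
        plus[k] += h
        minus[k] -= h
        grad[k] = (
            loss(NetworkWeights.unpack(plus, sizes), X, y, l2, task)
            - loss(NetworkWeights.unpack(minus, sizes), X, y, l2, task)
        ) / (2 * h)
    return grad


class TestInit:
    def test_glorot_bound(self):
        net = _rand_net(SIZES_REG)
        bound = np.sqrt(6.0 / (9 + 5))
        assert np.all(np.abs(net.weights[0]) <= bound)
        assert np.abs(net.weights[0]).max() > 0.5 * bound  # actually fills the range

    def test_biases_zero(self):
        net = _rand_net(SIZES_CLF)
        assert all(np.all(b == 0.0) for b in net.biases)

    def test_deterministic_per_seed(self):
        a, b = _rand_net(SIZES_REG, 7), _rand_net(SIZES_REG, 7)
        np.testing.assert_array_equal(a.pack(), b.pack())


class TestForward:
    def test_zero_weights_regression_outputs_bias(self):
        net = NetworkWeights(
            weights=[np.zeros((9, 5)), np.zeros((5, 3)), np.zeros((3, 1))],
            biases=[np.zeros(5), np.zeros(3), np.full(1, 2.5)],
        )
        out = forward(net, np.random.default_rng(0).normal(size=(11, 9)))
        np.testing.assert_allclose(out, 2.5)

    def test_softmax_symmetry_and_normalization(self):
        net = NetworkWeights(
            weights=[np.zeros((9, 5)), np.zeros((5, 3)), np.zeros((3, 3))],
            biases=[np.zeros(5), np.zeros(3), np.zeros(3)],
        )
        probs = forward(net, np.zeros((4, 9)), "classification")
        np.testing.assert_allclose(probs, 1 / 3)
        net2 = _rand_net(SIZES_CLF, 3)
        probs2 = forward(net2, np.random.default_rng(4).normal(size=(200, 9)), "classification")
        np.testing.assert_allclose(probs2.sum(axis=1), 1.0, atol=1e-12)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            forward(_rand_net(SIZES_REG), np.zeros((5, 4)))


class TestLoss:
    def test_perfect_regression_zero_loss(self):
        net = _rand_net(SIZES_REG, 1)
        X = np.random.default_rng(2).normal(size=(20, 9))
        y = forward(net, X)
        assert loss(net, X, y, l2=0.0) == pytest.approx(0.0, abs=1e-15)

    def test_uniform_classifier_cross_entropy_is_ln3(self):
        net = NetworkWeights(
            weights=[np.zeros((9, 5)), np.zeros((5, 3)), np.zeros((3, 3))],
            biases=[np.zeros(5), np.zeros(3), np.zeros(3)],
        )
        X = np.random.default_rng(0).normal(size=(30, 9))
        y = np.random.default_rng(1).integers(0, 3, size=30)
        assert loss(net, X, y, 0.0, "classification") == pytest.approx(np.log(3))

    def test_penalty_strictly_additive(self):
        net = _rand_net(SIZES_REG, 5)
        X = np.random.default_rng(3).normal(size=(15, 9))
        y = np.random.default_rng(4).normal(size=15)
        assert loss(net, X, y, 0.001) > loss(net, X, y, 0.0)
        extra = loss(net, X, y, 0.002) - loss(net, X, y, 0.001)
        assert extra == pytest.approx(0.001 * net.squared_norm())


class TestGradient:
    @pytest.mark.parametrize("task, sizes", [("regression", SIZES_REG), ("classification", SIZES_CLF)])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_finite_differences(self, task, sizes, seed):
        rng = np.random.default_rng(seed)
        net = init_glorot(sizes, rng)
        # nonzero biases keep pre-activations off the exact ReLU kink, where
        # the subgradient convention and finite differences legitimately differ
        net.biases = [rng.normal(0, 0.1, b.shape) for b in net.biases]
        X = rng.normal(size=(12, 9))
        y = rng.normal(size=12) if task == "regression" else rng.integers(0, 3, size=12)
        analytic = gradient(net, X, y, 0.001, task).pack()
        numeric = _finite_difference(net, X, y, 0.001, task)
        scale = np.maximum(np.abs(numeric), 1.0)
        assert np.max(np.abs(analytic - numeric) / scale) < 1e-5

    def test_zero_at_perfect_fit_without_penalty(self):
        net = _rand_net(SIZES_REG, 8)
        X = np.random.default_rng(9).normal(size=(25, 9))
        y = forward(net, X)
        g = gradient(net, X, y, 0.0).pack()
        np.testing.assert_allclose(g, 0.0, atol=1e-12)

    def test_penalty_gradient_linear_in_lambda(self):
        net = _rand_net(SIZES_REG, 6)
        X = np.random.default_rng(10).normal(size=(10, 9))
        y = np.random.default_rng(11).normal(size=10)
        g0 = gradient(net, X, y, 0.0).pack()
        g1 = gradient(net, X, y, 0.01).pack()
        g2 = gradient(net, X, y, 0.02).pack()
        np.testing.assert_allclose(g2 - g0, 2 * (g1 - g0), atol=1e-12)


class TestTraining:
    def _linear_data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 9))
        w = rng.normal(size=9)
        return X, X @ w

    def test_recovers_representable_linear_function(self):
        X, y = self._linear_data()
        fitted = train_lbfgs(X, y, l2=0.0, rng=np.random.default_rng(0), max_iter=2000, patience=50)
        resid = forward(fitted.weights, X) - y
        assert np.mean(resid**2) < 1e-4 * np.var(y)

    def test_deterministic_per_seed(self):
        X, y = self._linear_data(n=80)
        a = train_lbfgs(X, y, rng=np.random.default_rng(5))
        b = train_lbfgs(X, y, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.weights.pack(), b.weights.pack())
        assert a.trace.n_iterations == b.trace.n_iterations

    def test_flat_landscape_stops_immediately(self):
        X = np.random.default_rng(0).normal(size=(40, 9))
        y = np.full(40, 3.0)
        zero_head = NetworkWeights(
            weights=[np.zeros((9, 5)), np.zeros((5, 3)), np.zeros((3, 1))],
            biases=[np.zeros(5), np.zeros(3), np.full(1, 3.0)],
        )
        fitted = train_lbfgs(
            X, y, l2=0.0, patience=1, rng=np.random.default_rng(1), initial_weights=zero_head
        )
        assert fitted.trace.n_iterations <= 2

    def test_final_train_loss_not_worse_than_init(self):
        X, y = self._linear_data(n=100, seed=3)
        rng_init = np.random.default_rng(21)
        init = init_glorot((9, 5, 3, 1), rng_init)
        fitted = train_lbfgs(
            X, y, rng=np.random.default_rng(21), initial_weights=init
        )
        assert loss(fitted.weights, X, y, 0.001) <= loss(init, X, y, 0.001)

    def test_larger_penalty_shrinks_weights(self):
        X, y = self._linear_data(n=150, seed=4)
        small = train_lbfgs(X, y, l2=0.0, rng=np.random.default_rng(2), patience=50)
        large = train_lbfgs(X, y, l2=0.1, rng=np.random.default_rng(2), patience=50)
        assert large.weights.squared_norm() < small.weights.squared_norm()


class TestEstimators:
    def test_regressor_target_scale_round_trip(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(120, 9))
        y = 1e6 * (X[:, 0] + 2 * X[:, 1])
        est = CompactMLPRegressor(target_scale=1e6, random_state=0, max_iter=2000, patience=50)
        est.fit(X, y)
        pred = est.predict(X)
        assert pred.shape == y.shape
        assert np.corrcoef(pred, y)[0, 1] > 0.99

    def test_classifier_probabilities_and_labels(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(150, 9))
        y = (X[:, 0] > 0).astype(int) + (X[:, 1] > 1).astype(int)
        est = CompactMLPClassifier(random_state=0).fit(X, y)
        probs = est.predict_proba(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert set(est.predict(X)) <= set(est.classes_)

    def test_permuting_rows_permutes_predictions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 9))
        y = X[:, 0]
        est = CompactMLPRegressor(random_state=3).fit(X, y)
        perm = rng.permutation(60)
        np.testing.assert_allclose(est.predict(X)[perm], est.predict(X[perm]))

    def test_estimator_json_round_trip(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 9))
        est = CompactMLPRegressor(random_state=0).fit(X, X[:, 0])
        clone = CompactMLPRegressor.from_dict(est.to_dict())
        np.testing.assert_array_equal(est.predict(X), clone.predict(X))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = CompactMLPRegressor(alpha=0.01, random_state=5)
        assert clone(est).get_params() == est.get_params()
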