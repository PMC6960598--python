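import numpy as np
import pytest

from ppgbp.neuralnet import (
    NetworkParams,
    NetworkTopology,
    TrainConfig,
    forward,
    init_params,
    rmse_fitness,
    sizing_range,
    train_lm,
)


class TestSizingRange:
    @pytest.mark.parametrize(
        "n,l,expected",
        [(14, 1, (5, 14)), (3, 1, (3, 12)), (24, 1, (6, 15))],
    )
    def test_empirical_rule(self, n, l, expected):
        assert sizing_range(n, l) == expected

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            sizing_range(0, 1)


class TestForward:
    def test_zero_weights_predict_descaled_bias(self, linear_toy):
        X, y = linear_toy
        topo = NetworkTopology(1, 3)
        p = init_params(X, y, topo, seed=0).with_vector(np.zeros(topo.n_params))
        beta = 0.25
        vec = np.zeros(topo.n_params)
        vec[-1] = beta
        p = p.with_vector(vec)
        expected = p.y_scale.inverse(np.array([[beta]]))[0, 0]
        np.testing.assert_allclose(forward(p, X), expected)

    def test_single_hidden_unit_matches_hand_computation(self):
        X = np.array([[0.3], [-0.6]])
        y = np.array([0.0, 1.0])
        topo = NetworkTopology(1, 1)
        p = init_params(X, y, topo, seed=0)
        w1, b1, w2, b2 = 0.7, -0.2, 1.3, 0.4
        p = p.with_vector(np.array([w1, b1, w2, b2]))
        xs = p.x_scale.transform(X).ravel()
        scaled = w2 * np.tanh(w1 * xs + b1) + b2
        expected = p.y_scale.inverse(scaled[:, None]).ravel()
        np.testing.assert_allclose(forward(p, X), expected, rtol=1e-12)

    def test_forward_is_deterministic(self, linear_toy):
        X, y = linear_toy
        p = init_params(X, y, NetworkTopology(1, 4), seed=3)
        np.testing.assert_array_equal(forward(p, X), forward(p, X))

    def test_dimension_mismatch_rejected(self, linear_toy):
        X, y = linear_toy
        p = init_params(X, y, NetworkTopology(1, 2), seed=0)
        with pytest.raises(ValueError):
            forward(p, np.ones((3, 2)))

    def test_parameter_roundtrip_is_bit_identical(self, linear_toy):
        X, y = linear_toy
        p = init_params(X, y, NetworkTopology(1, 5), seed=1)
        q = p.with_vector(p.vector.copy())
        np.testing.assert_array_equal(forward(p, X), forward(q, X))

    def test_json_roundtrip(self, linear_toy):
        X, y = linear_toy
        p = init_params(X, y, NetworkTopology(1, 2), seed=4)
        q = NetworkParams.from_json(p.to_json())
        np.testing.assert_allclose(forward(p, X), forward(q, X), rtol=1e-12)


class TestScaling:
    def test_minmax_maps_training_extremes_to_unit_interval(self, linear_toy):
        X, y = linear_toy
        p = init_params(X, y, NetworkTopology(1, 2), seed=0)
        xs = p.x_scale.transform(X)
        assert xs.min() == pytest.approx(-1.0)
        assert xs.max() == pytest.approx(1.0)
        np.testing.assert_allclose(p.x_scale.inverse(xs), X, rtol=1e-12)


class TestTraining:
    def test_linear_law_learned_to_high_precision(self, linear_toy):
        X, y = linear_toy
        cfg = TrainConfig(max_epochs=200, goal_mse=1e-12, seed=0)
        p = train_lm(X, y, NetworkTopology(1, 1), cfg)
        assert rmse_fitness(p, X, y) < 1e-3

    def test_constant_target_absorbed_by_bias(self):
        X = np.linspace(0, 1, 20)[:, None]
        y = np.full(20, 7.0)
        p = train_lm(
            X, y, NetworkTopology(1, 2), TrainConfig(goal_mse=1e-18, seed=1)
        )
        assert rmse_fitness(p, X, y) < 1e-6

    def test_same_seed_gives_identical_parameters(self, linear_toy):
        X, y = linear_toy
        cfg = TrainConfig(max_epochs=50, seed=5)
        p1 = train_lm(X, y, NetworkTopology(1, 3), cfg)
        p2 = train_lm(X, y, NetworkTopology(1, 3), cfg)
        np.testing.assert_array_equal(p1.vector, p2.vector)

    def test_nan_in_data_rejected(self):
        with pytest.raises(ValueError):
            train_lm(
                np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]),
                NetworkTopology(1, 1),
            )

    def test_lm_matches_gradient_descent_oracle(self):
        """LM and a slow numerical-gradient descent agree on a small toy."""
        rng = np.random.default_rng(7)
        X = rng.uniform(-2, 2, (30, 2))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        topo = NetworkTopology(2, 3)
        lm = train_lm(X, y, topo, TrainConfig(max_epochs=300, seed=2))

        # oracle: numerical-gradient descent on the same scaled problem
        start = init_params(X, y, topo, seed=2)
        xs = start.x_scale.transform(X)
        ys = start.y_scale.transform(y[:, None]).ravel()

        def mse(vec):
            p = start.with_vector(vec)
            w1, b1, w2, b2 = p.unpack()
            pred = np.tanh(xs @ w1.T + b1) @ w2 + b2
            return np.mean((ys - pred) ** 2)

        vec = start.vector.copy()
        h = 1e-6
        for _ in range(4000):
            grad = np.array([
                (mse(vec + h * e) - mse(vec - h * e)) / (2 * h)
                for e in np.eye(vec.size)
            ])
            vec -= 0.5 * grad
        oracle = start.with_vector(vec)
        assert rmse_fitness(lm, X, y) <= 1.1 * rmse_fitness(oracle, X, y) + 1e-9


class TestRmse:
    def test_perfect_prediction_scores_zero(self, linear_toy):
        X, y = linear_toy
        p = train_lm(X, y, NetworkTopology(1, 1), TrainConfig(seed=0))
        assert rmse_fitness(p, X, forward(p, X)) == 0.0

    def test_hand_arithmetic(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([1.0, 2.0])
        topo = NetworkTopology(1, 1)
        p = init_params(X, y, topo, seed=0).with_vector(np.zeros(4))
        # zero network predicts the de-scaled 0 = midrange = 1.5 for both
        err = y - forward(p, X)
        np.testing.assert_allclose(np.abs(err), [0.5, 0.5])
        assert rmse_fitness(p, X, y) == pytest.approx(0.5)

    def test_empty_input_rejected(self, linear_toy):
        X, y = linear_toy
        p = init_params(X, y, NetworkTopology(1, 1), seed=0)
        with pytest.raises(ValueError):
            rmse_fitness(p, np.empty((0, 1)), np.empty(0))
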