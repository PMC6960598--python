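import numpy as np
import pytest

from ppgbp.ensemble import (
    EnsembleModel,
    N_BASE_MODELS,
    calibrate_individual,
    predict,
    train_base_models,
)
from ppgbp.mpga import GAConfig
from ppgbp.neuralnet import NetworkTopology, TrainConfig, forward


FAST_GA = GAConfig(seed=0, max_generations=6)
FAST_CAL = GAConfig(
    n_populations=4, bits_per_variable=25, seed=0, max_generations=12
)


def _linear_data(seed, n=100):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.5, 1.5, (n, 3))
    y = 80.0 + 30.0 * X[:, 0] - 20.0 * X[:, 1] + rng.normal(0, 0.5, n)
    return X, y


@pytest.fixture(scope="module")
def base_nets():
    X, y = _linear_data(0)
    nets, fold_rmse = train_base_models(
        X, y, NetworkTopology(3, 2), FAST_GA,
        TrainConfig(max_epochs=60, seed=0), seed=0,
    )
    return X, y, nets, fold_rmse


def _model(nets):
    return EnsembleModel(
        nets_sbp=nets, nets_dbp=nets, feature_names=("f0", "f1", "f2")
    )


class TestTrainBaseModels:
    def test_five_models_with_balanced_folds(self, base_nets):
        X, y, nets, fold_rmse = base_nets
        assert len(nets) == N_BASE_MODELS
        assert len(fold_rmse) == N_BASE_MODELS
        assert all(np.isfinite(r) for r in fold_rmse)

    def test_constant_target_learned_by_every_fold(self):
        X, _ = _linear_data(1, n=60)
        y = np.full(60, 95.0)
        nets, _ = train_base_models(
            X, y, NetworkTopology(3, 1), FAST_GA,
            TrainConfig(max_epochs=30, goal_mse=1e-16, seed=1), seed=1,
        )
        for net in nets:
            np.testing.assert_allclose(forward(net, X), 95.0, atol=0.01)

    def test_fold_assignment_reproducible(self):
        X, y = _linear_data(2, n=60)
        kw = dict(
            topo=NetworkTopology(3, 1),
            ga_cfg=GAConfig(seed=2, max_generations=3),
            train_cfg=TrainConfig(max_epochs=20, seed=2),
            seed=2,
        )
        n1, r1 = train_base_models(X, y, kw["topo"], kw["ga_cfg"],
                                   kw["train_cfg"], seed=kw["seed"])
        n2, r2 = train_base_models(X, y, kw["topo"], kw["ga_cfg"],
                                   kw["train_cfg"], seed=kw["seed"])
        assert r1 == r2
        for a, b in zip(n1, n2):
            np.testing.assert_array_equal(a.vector, b.vector)

    def test_too_few_samples_rejected(self):
        X, y = _linear_data(3, n=30)
        with pytest.raises(ValueError):
            train_base_models(X, y, NetworkTopology(3, 1), FAST_GA)


class TestCalibration:
    def test_calibration_beats_the_best_single_model_bound(self, base_nets):
        X, y, nets, _ = base_nets
        model = _model(nets)
        cal_X, cal_y = X[:6], y[:6]
        calibrate_individual(model, "ind1", cal_X, cal_y, cal_y, FAST_CAL)
        a, _ = model.coefficients["ind1"]
        ens_rmse = float(np.sqrt(np.mean(
            (np.column_stack([forward(n, cal_X) for n in nets]) @ a - cal_y) ** 2
        )))
        singles = [
            float(np.sqrt(np.mean((forward(n, cal_X) - cal_y) ** 2)))
            for n in nets
        ]
        assert ens_rmse <= min(singles) + 0.5

    def test_coefficients_stay_inside_coding_range(self, base_nets):
        X, y, nets, _ = base_nets
        model = _model(nets)
        calibrate_individual(model, "ind2", X[:6], y[:6], y[:6], FAST_CAL)
        for coeff in model.coefficients["ind2"]:
            assert coeff.min() >= -0.5 - 1e-12
            assert coeff.max() <= 0.8 + 1e-12

    def test_calibrated_beats_equal_weights_on_calibration_set(self, base_nets):
        X, y, nets, _ = base_nets
        for seed in range(3):
            model = _model(nets)
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(X), 6, replace=False)
            cal_X, cal_y = X[idx], y[idx]
            cfg = GAConfig(
                n_populations=4, bits_per_variable=25, seed=seed,
                max_generations=12,
            )
            calibrate_individual(model, "s", cal_X, cal_y, cal_y, cfg)
            a, _ = model.coefficients["s"]
            preds = np.column_stack([forward(n, cal_X) for n in nets])
            cal_rmse = float(np.sqrt(np.mean((preds @ a - cal_y) ** 2)))
            eq_rmse = float(np.sqrt(np.mean(
                (preds @ np.full(5, 0.2) - cal_y) ** 2
            )))
            assert cal_rmse <= eq_rmse + 1e-4  # coding-quantization slack

    def test_too_few_calibration_records_rejected(self, base_nets):
        X, y, nets, _ = base_nets
        with pytest.raises(ValueError):
            calibrate_individual(_model(nets), "x", X[:1], y[:1], y[:1], FAST_CAL)


class TestPredict:
    def test_single_model_coefficients_reduce_to_that_model(self, base_nets):
        X, y, nets, _ = base_nets
        model = _model(nets)
        one = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        model.coefficients["ind"] = (one, one)
        sbp, dbp = predict(model, "ind", X[:5])
        np.testing.assert_allclose(sbp, forward(nets[0], X[:5]), rtol=1e-12)
        np.testing.assert_allclose(dbp, forward(nets[0], X[:5]), rtol=1e-12)

    def test_zero_coefficients_trigger_plausibility_warning(self, base_nets):
        X, _, nets, _ = base_nets
        model = _model(nets)
        zero = np.zeros(5)
        model.coefficients["ind"] = (zero, zero)
        with pytest.warns(UserWarning, match="40 mmHg"):
            sbp, _ = predict(model, "ind", X[:3])
        np.testing.assert_allclose(sbp, 0.0)

    def test_uncalibrated_individual_named_in_error(self, base_nets):
        X, _, nets, _ = base_nets
        with pytest.raises(KeyError, match="ghost"):
            predict(_model(nets), "ghost", X[:2])

    def test_json_roundtrip_preserves_predictions(self, base_nets):
        X, y, nets, _ = base_nets
        model = _model(nets)
        model.coefficients["ind"] = (np.full(5, 0.2), np.full(5, 0.2))
        clone = EnsembleModel.from_json(model.to_json())
        s1, d1 = predict(model, "ind", X[:4])
        s2, d2 = predict(clone, "ind", X[:4])
        np.testing.assert_allclose(s1, s2, rtol=1e-12)
        np.testing.assert_allclose(d1, d2, rtol=1e-12)
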