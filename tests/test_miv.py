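import numpy as np
import pandas as pd
import pytest

from ppgbp.miv import contributions, miv_scores, screen, two_round_screen
from ppgbp.neuralnet import NetworkTopology, TrainConfig, init_params


def _tiny_linear_net(X, y, weights):
    """Network operating deep in the linear region of tanh."""
    topo = NetworkTopology(X.shape[1], 1)
    p = init_params(X, y, topo, seed=0)
    eps = 1e-4
    vec = np.concatenate([eps * np.asarray(weights), [0.0], [1.0 / eps], [0.0]])
    return p.with_vector(vec)


class TestMivScores:
    def test_ignored_feature_has_zero_impact(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(1.0, 2.0, (50, 3))
        y = X[:, 0]
        net = _tiny_linear_net(X, y, [1.0, 0.0, 0.5])
        miv = miv_scores(net, X)
        assert miv[1] == pytest.approx(0.0, abs=1e-12)

    def test_linear_network_matches_analytic_value(self):
        """For an (effectively) linear map, MIV_j = 0.2 * w_eff_j * mean x_j."""
        rng = np.random.default_rng(1)
        X = rng.uniform(1.0, 3.0, (200, 3))
        y = X @ np.array([2.0, -1.0, 0.5])
        net = _tiny_linear_net(X, y, [1.0, -0.4, 0.7])
        miv = miv_scores(net, X)
        # effective original-units slope: chain rule through both scalings
        w_scaled = np.array([1.0, -0.4, 0.7])  # hidden->output gain cancels eps
        w_eff = w_scaled * (2.0 / net.x_scale.span) * (net.y_scale.span[0] / 2.0)
        expected = 0.2 * w_eff * X.mean(axis=0)
        np.testing.assert_allclose(miv, expected, rtol=0.01)

    def test_duplicated_columns_share_impact(self):
        rng = np.random.default_rng(2)
        col = rng.uniform(1.0, 2.0, 80)
        X = np.column_stack([col, col])
        net = _tiny_linear_net(X, col, [0.6, 0.6])
        miv = miv_scores(net, X)
        assert miv[0] == pytest.approx(miv[1], rel=1e-9)

    def test_dimension_mismatch_rejected(self):
        X = np.ones((10, 2))
        net = _tiny_linear_net(X, X[:, 0], [1.0, 1.0])
        with pytest.raises(ValueError):
            miv_scores(net, np.ones((10, 3)))


class TestContributions:
    def test_single_feature_takes_all(self):
        table = contributions(np.array([3.2]), ["only"])
        assert table["contribution"].iloc[0] == 1.0
        assert table["cumulative"].iloc[0] == 1.0

    def test_normalization_and_monotonicity(self):
        rng = np.random.default_rng(3)
        miv = rng.normal(size=12)
        table = contributions(miv)
        assert table["contribution"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(table["cumulative"]) >= -1e-12).all()
        assert table["cumulative"].iloc[-1] == pytest.approx(1.0, abs=1e-9)
        assert sorted(table["rank"]) == list(range(1, 13))

    def test_ranking_is_by_absolute_value(self):
        table = contributions(np.array([-5.0, 1.0, 3.0]), ["a", "b", "c"])
        assert table["feature"].tolist() == ["a", "c", "b"]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            contributions(np.zeros(4))


class TestContributionProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.floats(
                min_value=-50.0, max_value=50.0,
                allow_nan=False, allow_infinity=False,
            ).filter(lambda v: abs(v) > 1e-6),
            min_size=1, max_size=30,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_normalization_holds_for_any_miv_vector(self, miv):
        table = contributions(np.array(miv))
        assert table["contribution"].sum() == pytest.approx(1.0, abs=1e-9)
        cum = table["cumulative"].to_numpy()
        assert (np.diff(cum) >= -1e-12).all()
        assert cum[-1] == pytest.approx(1.0, abs=1e-9)
        # screening is monotone in the threshold for every ranking
        sizes = [len(screen(table, t)) for t in (0.2, 0.5, 0.8, 0.99)]
        assert sizes == sorted(sizes)


class TestScreen:
    def test_near_unit_threshold_keeps_everything(self):
        table = contributions(np.array([4.0, 2.0, 1.0]))
        assert len(screen(table, 1.0 - 1e-9)) == 3

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        table = contributions(rng.uniform(0.1, 5.0, 15))
        sizes = [len(screen(table, t)) for t in np.linspace(0.05, 0.99, 20)]
        assert sizes == sorted(sizes)

    def test_smallest_sufficient_prefix(self):
        table = contributions(np.array([6.0, 3.0, 1.0]))  # cum .6, .9, 1.0
        assert screen(table, 0.85) == ["x0", "x1"]
        assert screen(table, 0.95) == ["x0", "x1", "x2"]

    def test_invalid_threshold_rejected(self):
        table = contributions(np.array([1.0]))
        with pytest.raises(ValueError):
            screen(table, 1.5)


class TestTwoRoundScreen:
    @staticmethod
    def _planted(seed, n=150):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.uniform(0.5, 1.5, (n, 8)),
            columns=[f"f{j}" for j in range(8)],
        )
        y = (
            40.0 * X["f1"] - 30.0 * X["f4"] + 25.0 * X["f6"]
            + rng.normal(0.0, 0.5, n)
        )
        return X, y

    def test_causal_features_survive(self):
        X, y = self._planted(0)
        result = two_round_screen(
            X, y, n_hidden=4,
            train_cfg=TrainConfig(max_epochs=100, seed=0),
            thresholds=(0.91, 0.89), seed=0,
        )
        assert {"f1", "f4", "f6"} <= set(result.selected)

    def test_lax_thresholds_keep_all(self):
        X, y = self._planted(1)
        result = two_round_screen(
            X, y, n_hidden=3,
            train_cfg=TrainConfig(max_epochs=60, seed=1),
            thresholds=(1 - 1e-9, 1 - 1e-9), seed=1,
        )
        assert set(result.selected) == set(X.columns)

    def test_fixed_seed_reproducible(self):
        X, y = self._planted(2)
        kw = dict(
            n_hidden=3, train_cfg=TrainConfig(max_epochs=60, seed=3),
            thresholds=(0.91, 0.89), seed=3,
        )
        r1 = two_round_screen(X, y, **kw)
        r2 = two_round_screen(X, y, **kw)
        assert r1.selected == r2.selected
        pd.testing.assert_frame_equal(r1.round2, r2.round2)
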