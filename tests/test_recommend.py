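import numpy as np
import pytest

import dbtlearn as dl
from dbtlearn.exceptions import ArgumentError, BoundsDegeneracyError, ConfigurationError
from dbtlearn.recommend import (
    InputBounds,
    ObjectiveConfig,
    TemperingLadder,
    default_bounds,
    relative_differences,
    sample_pi,
    select_recommendations,
    surrogate_G,
    surrogate_values,
)

KS_CRIT_1PCT = 1.628 / np.sqrt(2000)  # asymptotic 1% critical value at n = 2000


def oracle_select(draws, g, train, gamma0, batch, bounds, floor=0.01, max_decays=5):
    """Step-by-step re-implementation of the greedy diverse selection."""
    d = draws.shape[1]
    gamma = gamma0
    for _ in range(max_decays + 1):
        accepted = []
        order = sorted(range(len(draws)), key=lambda i: (-g[i], i))
        for i in order:
            refs = [row for row in train] + [draws[j] for j in accepted]
            ok = not refs
            for f in range(d):
                denom_ok = all(
                    abs(draws[i][f] - r[f])
                    / max(abs(r[f]), 0.01 * (bounds.upper[f] - bounds.lower[f]))
                    >= gamma
                    for r in refs
                )
                if refs and denom_ok:
                    ok = True
                    break
            if ok:
                accepted.append(i)
            if len(accepted) == batch:
                return accepted, gamma
        new_gamma = max(gamma / 2.0, floor)
        if new_gamma == gamma:
            return accepted, gamma
        gamma = new_gamma
    return accepted, gamma


class TestSurrogate:
    def test_alpha_zero_is_predictive_mean(self, fe_model):
        obj = ObjectiveConfig(mode="maximize", alpha=0.0)
        X = np.random.default_rng(0).uniform(0, 10, size=(20, 2))
        mean, _ = fe_model.predict_moments(X)
        np.testing.assert_allclose(surrogate_values(X, fe_model, obj), mean, atol=1e-12)

    def test_alpha_one_is_predictive_sd(self, fe_model):
        obj = ObjectiveConfig(mode="maximize", alpha=1.0)
        X = np.random.default_rng(1).uniform(0, 10, size=(20, 2))
        _, var = fe_model.predict_moments(X)
        np.testing.assert_allclose(
            surrogate_values(X, fe_model, obj), np.sqrt(var), atol=1e-12
        )

    def test_minimize_negates_mean(self, fe_model):
        x = np.array([3.0, 3.0])
        g_max = surrogate_G(x, fe_model, ObjectiveConfig(mode="maximize", alpha=0.0))
        g_min = surrogate_G(x, fe_model, ObjectiveConfig(mode="minimize", alpha=0.0))
        assert g_min == pytest.approx(-g_max)

    def test_specification_zero_at_target(self, fe_model, stub_model_factory):
        stub = stub_model_factory(lambda X: X.sum(axis=1), dim=2)
        obj = ObjectiveConfig(mode="specification", alpha=0.0, target=7.0, batch_size=1)
        assert surrogate_G(np.array([3.0, 4.0]), stub, obj) == pytest.approx(0.0)
        assert surrogate_G(np.array([0.0, 0.0]), stub, obj) == pytest.approx(-49.0)

    def test_specification_requires_target(self):
        with pytest.raises(ConfigurationError):
            ObjectiveConfig(mode="specification", target=None)
        with pytest.raises(ConfigurationError):
            ObjectiveConfig(mode="maximize", target=3.0)


class TestDefaultBounds:
    def test_min_max(self):
        ts = dl.TrainingSet(
            np.array([[0.0], [1.0]]), np.zeros((2, 1)), ["f"], ["y"]
        )
        b = default_bounds(ts, margin=0.0)
        assert (b.lower[0], b.upper[0]) == (0.0, 1.0)

    def test_margin_widens(self):
        ts = dl.TrainingSet(np.array([[0.0], [1.0]]), np.zeros((2, 1)), ["f"], ["y"])
        b = default_bounds(ts, margin=0.1)
        assert b.lower[0] == pytest.approx(-0.1)
        assert b.upper[0] == pytest.approx(1.1)

    def test_constant_feature_without_margin_errors(self):
        ts = dl.TrainingSet(
            np.array([[2.0, 0.0], [2.0, 1.0]]), np.zeros((2, 1)), ["c", "f"], ["y"]
        )
        with pytest.raises(BoundsDegeneracyError, match="c"):
            default_bounds(ts, margin=0.0)

    def test_invalid_bounds(self):
        with pytest.raises(ArgumentError):
            InputBounds(np.array([1.0]), np.array([1.0]))


class TestSamplePi:
    def test_constant_surrogate_gives_uniform_draws(self, stub_model_factory):
        """With flat G the target reduces to the uniform prior on the box."""
        stub = stub_model_factory(lambda X: np.zeros(len(X)), dim=2)
        obj = ObjectiveConfig(
            mode="maximize", alpha=0.0, bounds=InputBounds([0.0, 0.0], [1.0, 1.0])
        )
        draws, _, _ = sample_pi(
            stub, obj, n_draws=20_000, burn_in=500, seed=5, step_fraction=0.5
        )
        thinned = draws[::10]  # decorrelate the chain before the iid KS test
        from scipy.stats import kstest

        for dim in range(2):
            stat = kstest(thinned[:, dim], "uniform").statistic
            assert stat < KS_CRIT_1PCT

    def test_unimodal_target_mode_recovery(self, stub_model_factory):
        x0 = np.array([0.6, 0.4])
        stub = stub_model_factory(lambda X: -50.0 * ((X - x0) ** 2).sum(axis=1), dim=2)
        obj = ObjectiveConfig(
            mode="maximize", alpha=0.0, bounds=InputBounds([0.0, 0.0], [1.0, 1.0])
        )
        draws, _, _ = sample_pi(stub, obj, n_draws=4000, burn_in=500, seed=6)
        for dim in range(2):
            hist, edges = np.histogram(draws[:, dim], bins=50, range=(0, 1))
            mode = 0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1])
            assert abs(mode - x0[dim]) < 0.05

    def test_bimodal_target_both_basins_visited(self, stub_model_factory):
        """Tempering lets the chain hop between two well-separated sharp peaks."""

        def g(X):
            x = X[:, 0]
            return 8.0 * (
                np.exp(-((x - 0.25) ** 2) / (2 * 0.03**2))
                + np.exp(-((x - 0.75) ** 2) / (2 * 0.03**2))
            )

        stub = stub_model_factory(g, dim=1)
        obj = ObjectiveConfig(mode="maximize", alpha=0.0, bounds=InputBounds([0.0], [1.0]))
        draws, _, diag = sample_pi(stub, obj, n_draws=6000, burn_in=1000, seed=7)
        frac_left = (draws[:, 0] < 0.5).mean()
        assert 0.05 <= frac_left <= 0.95

    def test_draws_within_bounds_and_seeded(self, fe_model, fe_training):
        obj = ObjectiveConfig(
            mode="maximize", alpha=0.3, bounds=default_bounds(fe_training)
        )
        a, ga, _ = sample_pi(fe_model, obj, n_draws=300, burn_in=100, seed=8)
        b, gb, _ = sample_pi(fe_model, obj, n_draws=300, burn_in=100, seed=8)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ga, gb)
        assert obj.bounds.contains(a).all()

    def test_sampling_finds_near_optimal_surrogate(self, fe_model, fe_training):
        """Modes of pi correspond to optima of G: sampled max ~ probe max."""
        bounds = dl.InputBounds([0.0, 0.0], [10.0, 10.0])
        obj = ObjectiveConfig(mode="maximize", alpha=0.0, bounds=bounds)
        draws, g_vals, _ = sample_pi(fe_model, obj, n_draws=1500, burn_in=300, seed=9)
        rng = np.random.default_rng(10)
        probe = bounds.lower + rng.random((10_000, 2)) * bounds.range
        g_probe = surrogate_values(probe, fe_model, obj)
        tol = 0.01 * (g_probe.max() - g_probe.min())
        assert g_vals.max() >= g_probe.max() - tol


class TestSelection:
    def bounds1d(self):
        return InputBounds([0.0], [2.0])

    def test_hand_worked_one_dimensional_case(self):
        """gamma=0.2 vs data x=1: 1.05 too close (5%), 1.3 and 0.7 accepted."""
        data = dl.TrainingSet(np.array([[1.0]]), np.zeros((1, 1)), ["x"], ["y"])
        draws = np.array([[1.05], [1.3], [0.7]])
        g = np.array([3.0, 2.0, 1.0])  # G descending in draw order
        obj = ObjectiveConfig(
            mode="maximize", gamma=0.2, batch_size=2, bounds=self.bounds1d()
        )
        batch = select_recommendations(draws, g, data, obj)
        np.testing.assert_array_equal(batch.inputs, [[1.3], [0.7]])
        assert batch.gamma_used == 0.2
        assert not batch.incomplete

    def test_no_training_data_returns_top_by_g_with_stable_ties(self):
        draws = np.array([[0.0], [10.0], [20.0], [30.0]])
        g = np.array([1.0, 5.0, 5.0, 0.5])
        obj = ObjectiveConfig(
            mode="maximize", gamma=0.011, batch_size=2, bounds=InputBounds([0.0], [30.0])
        )
        batch = select_recommendations(draws, g, None, obj)
        np.testing.assert_array_equal(batch.inputs, [[10.0], [20.0]])

    def test_gamma_decays_when_draws_clash_with_data(self):
        data = dl.TrainingSet(np.array([[1.0]]), np.zeros((1, 1)), ["x"], ["y"])
        draws = np.ones((5, 1))  # all identical to the data point
        g = np.arange(5.0)[::-1]
        obj = ObjectiveConfig(
            mode="maximize", gamma=0.2, batch_size=3, bounds=self.bounds1d()
        )
        with pytest.warns(UserWarning, match="diverse"):
            batch = select_recommendations(draws, g, data, obj)
        assert batch.incomplete
        assert batch.gamma_used < 0.2
        assert len(batch) == 0

    def test_surrogate_values_sorted_non_increasing(self):
        rng = np.random.default_rng(20)
        draws = rng.uniform(0, 10, size=(40, 2))
        g = rng.normal(size=40)
        obj = ObjectiveConfig(
            mode="maximize", gamma=0.05, batch_size=8,
            bounds=InputBounds([0.0, 0.0], [10.0, 10.0]),
        )
        batch = select_recommendations(draws, g, None, obj)
        assert (np.diff(batch.surrogate_values) <= 1e-12).all()

    @pytest.mark.parametrize("case_seed", range(8))
    def test_greedy_matches_exhaustive_oracle(self, case_seed):
        """Greedy selection equals a step-by-step oracle on small instances."""
        rng = np.random.default_rng(100 + case_seed)
        d = int(rng.integers(1, 4))
        n_draws = int(rng.integers(5, 51))
        n_refs = int(rng.integers(0, 6))
        bounds = InputBounds(np.zeros(d), np.full(d, 10.0))
        draws = rng.uniform(0, 10, size=(n_draws, d))
        g = rng.normal(size=n_draws)
        gamma = float(rng.uniform(0.05, 0.5))
        batch = int(rng.integers(1, 6))
        train = rng.uniform(0, 10, size=(n_refs, d))
        data = (
            dl.TrainingSet(train, np.zeros((n_refs, 1)),
                           [f"x{i}" for i in range(d)], ["y"])
            if n_refs
            else None
        )
        obj = ObjectiveConfig(
            mode="maximize", gamma=gamma, batch_size=batch, bounds=bounds
        )
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            result = select_recommendations(draws, g, data, obj)
        idx, gamma_used = oracle_select(draws, g, train, gamma, batch, bounds)
        np.testing.assert_array_equal(result.inputs, draws[idx])
        assert result.gamma_used == pytest.approx(gamma_used)


class TestRecommendEndToEnd:
    def test_batch_contract_and_bounds(self, fe_model, fe_training):
        obj = ObjectiveConfig(mode="maximize", alpha=0.9, batch_size=16,
                              bounds=dl.InputBounds([0.0, 0.0], [10.0, 10.0]))
        batch = dl.recommend(fe_model, fe_training, obj, seed=3,
                             n_draws=3000, burn_in=500)
        assert len(batch) == 16
        assert obj.bounds.contains(batch.inputs).all()
        assert len(batch.predictions) == 16
        assert 0.0 <= batch.success_prob <= 1.0

    def test_gamma_rule_verified_by_brute_force(self, fe_model, fe_training):
        """Every recommendation passes the exists-feature/all-references rule."""
        bounds = dl.InputBounds([0.0, 0.0], [10.0, 10.0])
        obj = ObjectiveConfig(mode="maximize", alpha=0.9, batch_size=16, bounds=bounds)
        batch = dl.recommend(fe_model, fe_training, obj, seed=3,
                             n_draws=3000, burn_in=500)
        gamma = batch.gamma_used
        for r, x in enumerate(batch.inputs):
            refs = np.vstack([fe_training.inputs, batch.inputs[:r]])
            ok = False
            for f in range(2):
                denom = np.maximum(np.abs(refs[:, f]), 0.01 * bounds.range[f])
                if (np.abs(x[f] - refs[:, f]) / denom >= gamma).all():
                    ok = True
                    break
            assert ok

    def test_same_seed_reproduces_batch(self, fe_model, fe_training):
        obj = ObjectiveConfig(mode="maximize", alpha=0.5, batch_size=4,
                              bounds=dl.InputBounds([0.0, 0.0], [10.0, 10.0]))
        a = dl.recommend(fe_model, fe_training, obj, seed=21, n_draws=400, burn_in=100)
        b = dl.recommend(fe_model, fe_training, obj, seed=21, n_draws=400, burn_in=100)
        np.testing.assert_array_equal(a.inputs, b.inputs)
        assert a.success_prob == b.success_prob

    def test_exploration_raises_uncertainty_of_top_pick(self, fe_model, fe_training):
        """Averaged over seeds, alpha=1 selects higher-SD inputs than alpha=0."""
        bounds = dl.InputBounds([0.0, 0.0], [10.0, 10.0])
        sds = {0.0: [], 1.0: []}
        for seed in range(10):
            for alpha in (0.0, 1.0):
                obj = ObjectiveConfig(mode="maximize", alpha=alpha, batch_size=1,
                                      bounds=bounds)
                batch = dl.recommend(fe_model, fe_training, obj, seed=seed,
                                     n_draws=300, burn_in=100, success_draws=500)
                sds[alpha].append(batch.predictions[0].sd)
        assert np.mean(sds[1.0]) >= np.mean(sds[0.0])


def test_tempering_ladder_validation():
    with pytest.raises(ArgumentError):
        TemperingLadder(np.array([2.0, 4.0]))
    with pytest.raises(ArgumentError):
        TemperingLadder(np.array([1.0, 1.0]))
    ladder = TemperingLadder()
    assert ladder.temperatures[0] == 1.0
    assert (np.diff(ladder.temperatures) > 0).all()
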