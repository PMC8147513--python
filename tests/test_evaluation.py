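"""Optimal frequency, the frequency-range metric, and sampling simulations."""

import numpy as np
import pytest

from dbstune.data import ObservationSet
from dbstune.evaluation import (
    bayesopt_progress,
    efficiency_report,
    fit_observations,
    frequency_range,
    optimal_frequency,
    select_equal_interval,
    simulate_equal_interval,
    simulate_random,
)
from dbstune.exceptions import InvalidParameterError
from dbstune.gp import PredictiveDistribution
from dbstune.patient import profile_ar1


def pred_of(grid, mu, sigma):
    grid = np.asarray(grid, dtype=float)
    return PredictiveDistribution(grid, np.asarray(mu, float), np.asarray(sigma, float))


class TestOptimalFrequency:
    def test_decreasing_mean_puts_optimum_at_top(self):
        grid = np.arange(10.0, 160.0, 5.0)
        pred = pred_of(grid, -grid, np.ones_like(grid))
        assert optimal_frequency(pred) == 155.0

    def test_flat_mean_ties_to_lowest(self):
        grid = np.arange(10.0, 160.0, 5.0)
        pred = pred_of(grid, np.zeros_like(grid), np.ones_like(grid))
        assert optimal_frequency(pred) == 10.0

    def test_gp_fit_of_known_curve_finds_its_argmin(self):
        p = profile_ar1()
        grid = np.arange(10.0, 160.0, 5.0)
        res = fit_observations(grid, p.true_rigidity(grid), seed=0)
        x_opt = optimal_frequency(res.predict(grid))
        truth = grid[np.argmin(p.true_rigidity(grid))]
        assert abs(x_opt - truth) <= 5.0


class TestFrequencyRange:
    def test_hand_built_v_shape(self):
        grid = np.array([10.0, 15.0, 20.0, 25.0, 30.0])
        pred = pred_of(grid, [3, 2, 1, 2, 3], [1, 1, 1, 1, 1])
        fr = frequency_range(pred)
        assert fr.x_opt == 20.0
        np.testing.assert_array_equal(fr.range_set, [15.0, 20.0, 25.0])
        assert fr.width == 10.0  # two grid steps
        assert fr.lower_distance == 5.0

    def test_constant_prediction_covers_whole_grid(self):
        grid = np.arange(10.0, 186.0, 5.0)
        pred = pred_of(grid, np.ones_like(grid), np.full_like(grid, 0.2))
        fr = frequency_range(pred)
        assert fr.width == 175.0
        assert fr.range_set.size == grid.size

    def test_vanishing_uncertainty_shrinks_width_to_zero(self):
        grid = np.arange(10.0, 60.0, 5.0)
        mu = np.abs(grid - 30.0)
        fr = frequency_range(pred_of(grid, mu, np.full_like(grid, 1e-12)))
        assert fr.width == 0.0 and fr.x_opt == 30.0

    def test_shrinking_sigma_never_widens_range(self):
        rng = np.random.default_rng(0)
        grid = np.arange(10.0, 186.0, 5.0)
        for _ in range(20):
            mu = rng.normal(size=grid.size)
            sigma = rng.uniform(0.1, 1.0, size=grid.size)
            w_full = frequency_range(pred_of(grid, mu, sigma)).width
            w_small = frequency_range(pred_of(grid, mu, 0.3 * sigma)).width
            assert w_small <= w_full + 1e-12

    def test_x_opt_always_inside_interval(self):
        rng = np.random.default_rng(1)
        grid = np.arange(10.0, 186.0, 5.0)
        for _ in range(10):
            pred = pred_of(
                grid, rng.normal(size=grid.size), rng.uniform(0.01, 1, grid.size)
            )
            fr = frequency_range(pred)
            assert fr.interval[0] <= fr.x_opt <= fr.interval[1]
            assert fr.lower_distance <= fr.width


def brute_force_like(ceiling=155.0, noiseless=True):
    p = profile_ar1()
    grid = np.arange(10.0, ceiling + 2.5, 5.0)
    obs = ObservationSet()
    rng = np.random.default_rng(0)
    for f in grid:
        y = p.true_rigidity(f) + (0 if noiseless else rng.normal(0, p.noise_sd))
        obs.add(f, y)
    return obs


class TestEqualInterval:
    def test_three_points_on_155_grid(self):
        # midpoint 82.5 rounds up to the nearest tested setting, 85 Hz
        sel = select_equal_interval(brute_force_like(), 3)
        np.testing.assert_array_equal(sel, [10.0, 85.0, 155.0])

    def test_two_points_are_the_endpoints(self):
        np.testing.assert_array_equal(
            select_equal_interval(brute_force_like(), 2), [10.0, 155.0]
        )

    def test_saturation_equals_full_grid(self):
        bf = brute_force_like()
        sel = select_equal_interval(bf, np.unique(bf.x).size)
        np.testing.assert_array_equal(sel, np.unique(bf.x))

    def test_saturated_fit_reproduces_full_data_width(self):
        bf = brute_force_like(noiseless=False)
        n = np.unique(bf.x).size
        fr = simulate_equal_interval(bf, n, seed=0)
        full = fit_observations(bf.x, bf.y, seed=0)
        fr_full = frequency_range(full.predict(np.unique(bf.x)))
        assert fr.width == pytest.approx(fr_full.width, abs=1e-9)

    def test_n_below_two_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_equal_interval(brute_force_like(), 1)


class TestRandomSampling:
    def test_single_rep_reports_zero_sd(self):
        out = simulate_random(brute_force_like(noiseless=False), 6, reps=1, rng=0)
        assert out["sd_width"] == 0.0

    def test_seed_reproducibility(self):
        bf = brute_force_like(noiseless=False)
        a = simulate_random(bf, 6, reps=3, rng=9)
        b = simulate_random(bf, 6, reps=3, rng=9)
        assert a["mean_width"] == b["mean_width"] and a["sd_width"] == b["sd_width"]

    def test_width_converges_with_more_samples(self):
        bf = brute_force_like(noiseless=False)
        means = [
            simulate_random(bf, n, reps=6, rng=0)["mean_width"] for n in (3, 24)
        ]
        full = frequency_range(
            fit_observations(bf.x, bf.y, seed=0).predict(np.unique(bf.x))
        ).width
        # large-n random fits approach the full brute-force width
        assert abs(means[1] - full) <= abs(means[0] - full) + 5.0


class TestEfficiencyReport:
    def test_bayesopt_column_has_one_row_per_measurement(self, ar1_session):
        prog = bayesopt_progress(ar1_session)
        n_expected = len(ar1_session.config.seeds) + ar1_session.config.iterations
        assert len(prog) == n_expected
        assert list(prog["n"]) == list(range(1, n_expected + 1))

    def test_report_combines_methods(self, ar1_session):
        bf = brute_force_like(noiseless=False)
        report = efficiency_report(
            bf=bf, session=ar1_session, n_values=[3, 6], reps=3, rng_seed=0
        )
        methods = set(report["method"])
        assert methods == {"equal_interval", "random", "bayesopt"}
        assert set(report.columns) >= {
            "method", "n", "rep", "width_hz", "lower_distance_hz", "x_opt_hz"
        }
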