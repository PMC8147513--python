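"""Probit-GP preference learning: likelihood, MAP fit, prediction."""

import itertools

import numpy as np
import pytest
from scipy.special import ndtr

from dbstune.kernels import KernelParams, kernel_matrix
from dbstune.preference import (
    PreferenceDataset,
    PreferenceGP,
    PreferencePair,
    preference_probability,
    preferred_frequency,
)
from dbstune.gp import PredictiveDistribution


class TestPreferenceProbability:
    def test_equal_values_give_half(self):
        assert preference_probability(0.3, 0.3) == pytest.approx(0.5)

    def test_sqrt2_gap_gives_phi_of_one(self):
        assert preference_probability(np.sqrt(2.0), 0.0) == pytest.approx(
            0.841345, abs=1e-6
        )

    def test_limits(self):
        assert preference_probability(1e6, 0.0) == pytest.approx(1.0)
        assert preference_probability(-1e6, 0.0) == pytest.approx(0.0)

    def test_translation_invariance(self):
        fa, fb, c = 0.7, -0.2, 13.4
        assert preference_probability(fa + c, fb + c) == pytest.approx(
            preference_probability(fa, fb), rel=1e-12
        )


class TestMAPFit:
    def test_single_pair_orders_latent_values(self, default_kernel):
        res = PreferenceGP([PreferencePair(90.0, 30.0)], default_kernel).fit(
            restarts=5, seed=0
        )
        ia = np.where(res.x_train == 90.0)[0][0]
        ib = np.where(res.x_train == 30.0)[0][0]
        assert res.f_map[ia] > res.f_map[ib]

    def test_chain_of_consistent_comparisons_reproduces_total_order(
        self, default_kernel
    ):
        # five settings, four comparisons forming a total order
        x = [20.0, 50.0, 80.0, 110.0, 140.0]
        ranking = [80.0, 110.0, 50.0, 140.0, 20.0]  # best to worst
        pairs = [PreferencePair(a, b) for a, b in zip(ranking[:-1], ranking[1:])]
        res = PreferenceGP(pairs, default_kernel).fit(restarts=10, seed=0)
        fitted = {f: v for f, v in zip(res.x_train, res.f_map)}
        values = [fitted[f] for f in ranking]
        assert all(u > v for u, v in zip(values[:-1], values[1:]))
        assert set(res.x_train) == set(x)

    def test_f_map_is_centered(self, default_kernel):
        pairs = [PreferencePair(90.0, 30.0), PreferencePair(90.0, 150.0)]
        res = PreferenceGP(pairs, default_kernel).fit(restarts=5, seed=0)
        assert np.mean(res.f_map) == pytest.approx(0.0, abs=1e-12)

    def test_map_log_posterior_beats_zero_vector(self, default_kernel):
        rng = np.random.default_rng(4)
        x = np.array([30.0, 70.0, 110.0, 150.0])
        for s in range(5):
            pairs = []
            for _ in range(6):
                i, j = rng.choice(4, size=2, replace=False)
                pairs.append(PreferencePair(x[i], x[j]))
            model = PreferenceGP(pairs, default_kernel)
            res = model.fit(restarts=5, seed=s)
            assert res.map_log_posterior >= model.log_posterior(
                np.zeros(model.m)
            ) - 1e-9

    def test_flipping_all_pairs_negates_f_map(self, default_kernel):
        pairs = [
            PreferencePair(90.0, 30.0),
            PreferencePair(90.0, 150.0),
            PreferencePair(150.0, 30.0),
        ]
        res = PreferenceGP(pairs, default_kernel).fit(restarts=10, seed=0)
        flipped = [PreferencePair(p.b, p.a) for p in pairs]
        res_f = PreferenceGP(flipped, default_kernel).fit(restarts=10, seed=1)
        np.testing.assert_allclose(res_f.f_map, -res.f_map, atol=1e-6)

    def test_exhaustive_consistent_comparisons_recover_true_order(self):
        # points separated by >= 2 ell, so the smoothing prior cannot force
        # near-ties between neighbours with opposite ranks
        kernel = KernelParams(nu=1.5, ell=15.0, signal_var=1.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = np.sort(rng.choice(np.arange(10.0, 186.0, 30.0), 5, replace=False))
            truth = rng.permutation(5)  # ranks
            pairs = []
            for i, j in itertools.combinations(range(5), 2):
                a, b = (x[i], x[j]) if truth[i] > truth[j] else (x[j], x[i])
                pairs.append(PreferencePair(a, b))
            res = PreferenceGP(pairs, kernel).fit(restarts=10, seed=0)
            assert np.array_equal(np.argsort(res.f_map), np.argsort(truth))

    def test_identical_frequency_pair_is_information_free(self, default_kernel):
        informative = [PreferencePair(90.0, 30.0)]
        with_dup = informative + [PreferencePair(90.0, 90.0)]
        r1 = PreferenceGP(informative, default_kernel).fit(restarts=5, seed=0)
        r2 = PreferenceGP(with_dup, default_kernel).fit(restarts=5, seed=0)
        np.testing.assert_allclose(r1.f_map, r2.f_map, atol=1e-8)


class TestPGPPredict:
    def _fitted(self, kernel):
        pairs = [
            PreferencePair(90.0, 30.0),
            PreferencePair(110.0, 90.0),
            PreferencePair(110.0, 150.0),
        ]
        return PreferenceGP(pairs, kernel).fit(restarts=10, seed=0)

    def test_matches_direct_dense_evaluation(self, default_kernel):
        res = self._fitted(default_kernel)
        grid = np.array([25.0, 60.0, 95.0, 120.0, 160.0])
        pred = res.predict(grid)
        K = kernel_matrix(res.x_train, res.x_train, default_kernel)
        ks = kernel_matrix(grid, res.x_train, default_kernel)
        mu_o = ks @ np.linalg.solve(K, res.f_map)
        Cinv = np.linalg.inv(res.C + 1e-8 * np.eye(res.model.m))
        var_o = default_kernel.signal_var - np.einsum(
            "gm,mg->g", ks, np.linalg.solve(K + Cinv, ks.T)
        )
        np.testing.assert_allclose(pred.mu, mu_o, atol=1e-8)
        np.testing.assert_allclose(pred.sigma, np.sqrt(np.maximum(var_o, 0)), atol=1e-8)

    def test_informative_comparisons_reduce_variance_at_train_points(
        self, default_kernel
    ):
        res = self._fitted(default_kernel)
        pred = res.predict(res.x_train)
        assert np.all(pred.sigma < np.sqrt(default_kernel.signal_var))

    def test_no_likelihood_information_recovers_prior_variance(self, default_kernel):
        # C -> 0 makes C^-1 diverge and the predictive variance revert to prior
        from dbstune.preference import PreferenceGPResults

        model = PreferenceGP([PreferencePair(90.0, 30.0)], default_kernel)
        res = PreferenceGPResults(model, np.zeros(model.m), np.zeros((model.m, model.m)), 0.0)
        pred = res.predict(np.array([60.0, 120.0]))
        np.testing.assert_allclose(
            pred.sigma, np.sqrt(default_kernel.signal_var), rtol=1e-3
        )


class TestPreferredFrequency:
    def test_unimodal_peak(self):
        grid = np.array([80.0, 85.0, 90.0, 95.0, 100.0])
        mu = np.array([0.1, 0.4, 0.9, 0.5, 0.2])
        pred = PredictiveDistribution(grid, mu, np.ones_like(mu))
        assert preferred_frequency(pred) == 90.0

    def test_flat_mean_ties_to_lowest(self):
        grid = np.arange(10.0, 60.0, 5.0)
        pred = PredictiveDistribution(grid, np.zeros_like(grid), np.ones_like(grid))
        assert preferred_frequency(pred) == 10.0


def test_dataset_csv_roundtrip(tmp_path):
    pairs = PreferenceDataset(
        [PreferencePair(90.0, 30.0, 1), PreferencePair(110.0, 90.0, 2)]
    )
    path = tmp_path / "prefs.csv"
    pairs.to_csv(path)
    back = PreferenceDataset.from_csv(path)
    assert [(p.a, p.b, p.step_index) for p in back] == [
        (p.a, p.b, p.step_index) for p in pairs
    ]
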