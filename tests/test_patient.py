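"""Virtual-patient generator: curve shapes, noise, torque synthesis, choices."""

import numpy as np
import pytest

from dbstune.exceptions import IntolerableFrequencyError, InvalidParameterError
from dbstune.patient import (
    RigidityCurve,
    ValueFunction,
    VirtualPatient,
    load_patient,
    profile_ar1,
    profile_ar2,
    save_patient,
)
from dbstune.signal import compute_romar


GRID = np.arange(10.0, 186.0, 5.0)


class TestRigidityCurveShapes:
    def test_all_amplitudes_zero_gives_constant(self):
        curve = RigidityCurve(
            r_off=0.9, dip10_amp=0, worsen_amp=0, benefit_amp=0, bump_amp=0
        )
        np.testing.assert_allclose(curve(GRID), 0.9)

    @pytest.mark.parametrize("profile", [profile_ar1, profile_ar2])
    def test_low_frequency_dip_beats_20_to_50(self, profile):
        p = profile()
        band = GRID[(GRID >= 20) & (GRID <= 50)]
        assert p.true_rigidity(10.0) < p.true_rigidity(band).min()

    def test_profile1_monotone_decreasing_above_80(self):
        p = profile_ar1()
        g = GRID[(GRID >= 80) & (GRID <= p.ceiling)]
        assert np.all(np.diff(p.true_rigidity(g)) < 0)
        # hence the true optimum sits at the tolerability ceiling
        tol = GRID[GRID <= p.ceiling]
        assert tol[np.argmin(p.true_rigidity(tol))] == p.ceiling

    def test_profile2_has_high_frequency_bump(self):
        p = profile_ar2()
        inside = p.true_rigidity(np.arange(130.0, 156.0, 5.0)).max()
        assert inside > p.true_rigidity(120.0)
        assert inside > p.true_rigidity(170.0)

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(InvalidParameterError):
            profile_ar1().true_rigidity(200.0)

    def test_rigidity_never_driven_negative_is_validated(self):
        with pytest.raises(InvalidParameterError):
            VirtualPatient(curve=RigidityCurve(r_off=0.5, benefit_amp=0.6))


class TestValueFunction:
    @pytest.mark.parametrize("profile", [profile_ar1, profile_ar2])
    def test_peak_at_lowest_frequency_reaching_80pct_benefit(self, profile):
        p = profile()
        grid = GRID[GRID <= p.ceiling]
        v_argmax = grid[np.argmax(p.value(grid))]
        lowest_80 = grid[p.normalized_benefit(grid) >= 0.8][0]
        assert abs(v_argmax - lowest_80) <= 5.0  # within one grid step

    @pytest.mark.parametrize("profile", [profile_ar1, profile_ar2])
    def test_preference_peak_below_rigidity_optimum(self, profile):
        p = profile()
        grid = GRID[GRID <= p.ceiling]
        assert grid[np.argmax(p.value(grid))] < grid[np.argmin(p.true_rigidity(grid))]


class TestMeasurement:
    def test_zero_noise_returns_truth(self):
        p = profile_ar1()
        quiet = VirtualPatient(curve=p.curve, noise_sd=0.0, ceiling=p.ceiling,
                               value_fn=p.value_fn)
        assert quiet.measure_romar(100.0, 0) == pytest.approx(
            p.true_rigidity(100.0)
        )

    def test_noise_sd_calibrated(self, ar1):
        rng = np.random.default_rng(0)
        draws = np.array([ar1.measure_romar(100.0, rng) for _ in range(1000)])
        assert draws.std(ddof=1) == pytest.approx(ar1.noise_sd, rel=0.10)

    def test_frequency_above_ceiling_raises(self, ar1):
        with pytest.raises(IntolerableFrequencyError):
            ar1.measure_romar(ar1.ceiling + 5.0, 0)

    def test_same_seed_same_measurement(self, ar1):
        assert ar1.measure_romar(90.0, 42) == ar1.measure_romar(90.0, 42)


class TestTorqueSynthesis:
    def test_zero_stiffness_and_viscosity_gives_zero_romar(self, ar1):
        trace = ar1.synth_torque_trace(
            100.0, stiffness=0.0, viscous=0.0, torque_noise_frac=0.0, rng=0
        )
        with pytest.warns(UserWarning):
            assert compute_romar(trace).value == 0.0

    def test_doubling_stiffness_doubles_romar(self, ar1):
        kw = dict(viscous=0.0, torque_noise_frac=0.0, rng=0)
        r1 = compute_romar(ar1.synth_torque_trace(100.0, stiffness=1.0, **kw)).value
        r2 = compute_romar(ar1.synth_torque_trace(100.0, stiffness=2.0, **kw)).value
        assert r2 == pytest.approx(2 * r1, rel=1e-6)

    def test_calibration_matches_true_rigidity(self, ar1):
        # mean RoMaR of seeded synthetic traces tracks the ground-truth curve
        rng = np.random.default_rng(1)
        vals = [
            compute_romar(ar1.synth_torque_trace(100.0, rng=rng)).value
            for _ in range(50)
        ]
        assert np.mean(vals) == pytest.approx(ar1.true_rigidity(100.0), rel=0.05)

    def test_trace_has_requested_shape(self, ar1):
        trace = ar1.synth_torque_trace(80.0, fs=500.0, duration=10.0, rng=0)
        assert trace.fs == 500.0
        assert trace.duration == pytest.approx(10.0)


class TestPreferenceChoice:
    def test_equal_value_is_a_coin_flip(self):
        p = profile_ar1()
        assert p.choice_probability(90.0, 90.0) == 0.5
        # a near-equal-value pair behaves as a (nearly) fair coin
        fa, fb = 100.0, 105.0
        rng = np.random.default_rng(0)
        wins = sum(p.choose_preference(fa, fb, rng).a == fa for _ in range(10_000))
        assert wins / 10_000 == pytest.approx(p.choice_probability(fa, fb), abs=0.02)
        assert p.choice_probability(fa, fb) == pytest.approx(0.5, abs=0.1)

    def test_zero_noise_is_deterministic(self):
        base = profile_ar1()
        p = VirtualPatient(
            curve=base.curve, noise_sd=base.noise_sd, ceiling=base.ceiling,
            value_fn=ValueFunction(
                lambda_se=base.value_fn.lambda_se, se_onset=base.value_fn.se_onset,
                se_slope=base.value_fn.se_slope, pref_noise=0.0,
            ),
        )
        hi, lo = 105.0, 30.0
        assert p.value(hi) > p.value(lo)
        rng = np.random.default_rng(0)
        assert all(p.choose_preference(hi, lo, rng).a == hi for _ in range(50))

    def test_same_seed_same_choice(self, ar1):
        a = ar1.choose_preference(100.0, 30.0, 7)
        b = ar1.choose_preference(100.0, 30.0, 7)
        assert (a.a, a.b) == (b.a, b.b)


def test_patient_json_roundtrip(tmp_path):
    p = profile_ar2(rng_seed=3)
    path = tmp_path / "patient.json"
    save_patient(p, path)
    q = load_patient(path)
    assert q.curve == p.curve
    assert q.value_fn == p.value_fn
    assert (q.noise_sd, q.ceiling, q.rng_seed, q.name) == (
        p.noise_sd, p.ceiling, p.rng_seed, p.name,
    )
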