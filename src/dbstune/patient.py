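"""Virtual patients: synthetic rigidity–frequency curves, noisy measurements,
torque traces, tolerability ceilings and probit preference choices.

A virtual patient's ground-truth rigidity curve over stimulation frequency
combines the qualitative features seen in akinetic-rigid Parkinson's
patients: a local dip near 10 Hz (low-frequency stimulation reduces rigidity
more than 20–50 Hz does), a worsening hump around 20–50 Hz, a steep logistic
benefit above roughly 60–80 Hz, and an optional non-monotonic bump in the
130–155 Hz band:

    r(f) = r_off − dip10_amp·G(f; dip10_center, dip10_width)
                 + worsen_amp·G(f; worsen_center, worsen_width)
                 − benefit_amp·L((f − benefit_center)/benefit_slope)
                 + bump_amp·G(f; bump_center, bump_width)

with G a unit-height Gaussian and L the logistic function. Measurements add
Gaussian noise; frequencies above the patient's tolerability ceiling raise
an intolerable-frequency event instead of returning a value.

The patient's *preference* value function rewards rigidity benefit and
penalizes high-frequency side effects:

    v(f) = nb(f) − lambda_se·softplus((f − se_onset)/se_slope),
    nb(f) = (r_off − r(f)) / benefit_amp     (normalized benefit),

so the value peaks near the lowest frequency achieving ~80% of the maximal
rigidity benefit — below the rigidity argmin, as patients report. Pairwise
choices are drawn from the probit model on v.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .exceptions import (
    IntolerableFrequencyError,
    InvalidParameterError,
)
from .preference import PreferencePair
from .signal import TorqueTrace, compute_romar

__all__ = [
    "RigidityCurve",
    "ValueFunction",
    "VirtualPatient",
    "profile_ar1",
    "profile_ar2",
    "get_profile",
    "load_patient",
    "save_patient",
]

FREQ_MIN, FREQ_MAX = 10.0, 185.0
PATIENT_FORMAT_VERSION = 1


def _gauss(f, center, width):
    return np.exp(-0.5 * ((f - center) / width) ** 2)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


def _softplus(z):
    return np.logaddexp(0.0, z)


@dataclass(frozen=True)
class RigidityCurve:
    """Parameters of the ground-truth rigidity–frequency curve (RoMaR units)."""

    r_off: float = 1.2
    dip10_amp: float = 0.15
    dip10_center: float = 10.0
    dip10_width: float = 8.0
    worsen_amp: float = 0.15
    worsen_center: float = 35.0
    worsen_width: float = 12.0
    benefit_amp: float = 0.6
    benefit_center: float = 85.0
    benefit_slope: float = 12.0
    bump_amp: float = 0.0
    bump_center: float = 142.5
    bump_width: float = 10.0

    def __call__(self, f):
        f = np.asarray(f, dtype=float)
        r = (
            self.r_off
            - self.dip10_amp * _gauss(f, self.dip10_center, self.dip10_width)
            + self.worsen_amp * _gauss(f, self.worsen_center, self.worsen_width)
            - self.benefit_amp * _logistic((f - self.benefit_center) / self.benefit_slope)
            + self.bump_amp * _gauss(f, self.bump_center, self.bump_width)
        )
        return r


@dataclass(frozen=True)
class ValueFunction:
    """Parameters of the patient's preference value function."""

    lambda_se: float = 0.34  # side-effect weight
    se_onset: float = 100.0  # Hz at which side effects start to bite
    se_slope: float = 15.0  # Hz softness of the side-effect onset
    pref_noise: float = 0.05  # probit choice-noise scale on the value axis


@dataclass
class VirtualPatient:
    """A synthetic patient for exercising the optimization pipeline.

    All stochastic methods take an explicit ``numpy`` Generator (or a seed);
    the same seed reproduces identical measurements, traces and choices.
    """

    curve: RigidityCurve = field(default_factory=RigidityCurve)
    noise_sd: float = 0.03  # RoMaR measurement noise (≈5% of curve range)
    ceiling: float = 155.0  # highest tolerated frequency, Hz
    value_fn: ValueFunction = field(default_factory=ValueFunction)
    rng_seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        grid = np.arange(FREQ_MIN, FREQ_MAX + 2.5, 5.0)
        if np.any(self.curve(grid) <= 0):
            raise InvalidParameterError("true rigidity must stay positive on [10, 185] Hz")
        if self.curve.benefit_amp >= self.curve.r_off:
            raise InvalidParameterError("benefit_amp must be below r_off")
        tol = grid[grid <= self.ceiling + 1e-9]
        v = self.value(tol)
        if np.sum(v >= v.max() - 1e-12) != 1:
            raise InvalidParameterError("value function must have a unique grid argmax")

    # ------------------------------------------------------------------ truth
    def true_rigidity(self, f):
        """Noise-free rigidity at frequency ``f`` (Hz within [10, 185])."""
        f_arr = np.asarray(f, dtype=float)
        if np.any(f_arr < FREQ_MIN - 1e-9) or np.any(f_arr > FREQ_MAX + 1e-9):
            raise InvalidParameterError(
                f"frequency outside the stimulation range [{FREQ_MIN}, {FREQ_MAX}] Hz"
            )
        r = self.curve(f_arr)
        return float(r) if np.isscalar(f) else r

    def normalized_benefit(self, f):
        """Rigidity benefit relative to the logistic benefit amplitude, ~[0, 1]."""
        f_arr = np.asarray(f, dtype=float)
        nb = (self.curve.r_off - self.curve(f_arr)) / self.curve.benefit_amp
        return float(nb) if np.isscalar(f) else nb

    def value(self, f):
        """Latent preference value v(f): benefit minus side-effect penalty."""
        f_arr = np.asarray(f, dtype=float)
        vf = self.value_fn
        v = self.normalized_benefit(f_arr) - vf.lambda_se * _softplus(
            (f_arr - vf.se_onset) / vf.se_slope
        )
        return float(v) if np.isscalar(f) else v

    # ----------------------------------------------------------- measurement
    def measure_romar(self, f: float, rng) -> float:
        """Noisy rigidity measurement; raises above the tolerability ceiling."""
        if f > self.ceiling + 1e-9:
            raise IntolerableFrequencyError(f)
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        value = self.true_rigidity(f) + rng.normal(0.0, self.noise_sd)
        return float(max(value, 0.0))

    def synth_torque_trace(
        self,
        f: float,
        fs: float = 1000.0,
        duration: float = 25.0,
        rom_deg: float = 40.0,
        movement_hz: float = 0.5,
        viscous_frac: float = 0.2,
        torque_noise_frac: float = 0.02,
        stiffness: float | None = None,
        viscous: float | None = None,
        rng=None,
    ) -> TorqueTrace:
        """Synthesize a manipulandum torque trace whose RoMaR matches the curve.

        The handle angle follows a ±``rom_deg`` sinusoid at ``movement_hz``;
        torque is a stiffness term proportional to angle plus a viscous term
        proportional to angular velocity plus white noise. With the default
        calibration the peak torque A solves 2A/π = true_rigidity(f), so the
        RoMaR computed from the trace reproduces the curve within a few
        percent in expectation. Passing ``stiffness``/``viscous`` explicitly
        bypasses the calibration.
        """
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        t = np.arange(int(round(duration * fs)) + 1) / fs
        rom_rad = np.deg2rad(rom_deg)
        omega = 2.0 * np.pi * movement_hz
        theta = rom_rad * np.sin(omega * t)
        theta_dot = rom_rad * omega * np.cos(omega * t)
        if stiffness is None or viscous is None:
            r_true = self.true_rigidity(f)
            amp_target = np.pi * r_true / 2.0  # peak torque giving RoMaR = r_true
            amp_visc = viscous_frac * amp_target
            amp_stiff = np.sqrt(amp_target**2 - amp_visc**2)
            stiffness = amp_stiff / rom_rad if stiffness is None else stiffness
            viscous = amp_visc / (rom_rad * omega) if viscous is None else viscous
            noise_sd = torque_noise_frac * amp_target
        else:
            amp = np.hypot(stiffness * rom_rad, viscous * rom_rad * omega)
            noise_sd = torque_noise_frac * amp
        torque = stiffness * theta + viscous * theta_dot
        if noise_sd > 0:
            torque = torque + rng.normal(0.0, noise_sd, size=t.size)
        meta = {"frequency_hz": f, "patient": self.name}
        return TorqueTrace(t, torque, fs, meta)

    # ------------------------------------------------------------ preference
    def choice_probability(self, f_current: float, f_previous: float) -> float:
        """Probability that the patient declares the current setting preferred.

        Φ((v(current) − v(previous)) / (√2·pref_noise)); equal values give
        exactly 0.5, and pref_noise → 0 recovers the deterministic choice
        of the higher-value frequency.
        """
        dv = self.value(f_current) - self.value(f_previous)
        noise = self.value_fn.pref_noise
        if noise <= 0:
            return 0.5 if dv == 0 else (1.0 if dv > 0 else 0.0)
        from scipy.special import ndtr

        return float(ndtr(dv / (np.sqrt(2.0) * noise)))

    def choose_preference(self, f_current: float, f_previous: float, rng) -> PreferencePair:
        """Probit choice between the current and the previous setting."""
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        p_current = self.choice_probability(f_current, f_previous)
        if rng.uniform() < p_current:
            return PreferencePair(a=f_current, b=f_previous)
        return PreferencePair(a=f_previous, b=f_current)

    # -------------------------------------------------------------- round-trip
    def to_dict(self) -> dict:
        return {
            "format_version": PATIENT_FORMAT_VERSION,
            "name": self.name,
            "rigidity_curve": asdict(self.curve),
            "noise_sd": self.noise_sd,
            "ceiling": self.ceiling,
            "value_fn": asdict(self.value_fn),
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VirtualPatient":
        return cls(
            curve=RigidityCurve(**d["rigidity_curve"]),
            noise_sd=float(d["noise_sd"]),
            ceiling=float(d["ceiling"]),
            value_fn=ValueFunction(**d["value_fn"]),
            rng_seed=int(d.get("rng_seed", 0)),
            name=str(d.get("name", "custom")),
        )


def profile_ar1(rng_seed: int = 0) -> VirtualPatient:
    """Akinetic-rigid profile 1: ceiling 155 Hz, steady benefit growth to the top.

    Rigidity dips at 10 Hz, worsens around 35 Hz, and — per this phenotype —
    keeps falling roughly in proportion to frequency all the way to the
    tolerability ceiling (a broad logistic that has not saturated by
    155 Hz), so the true argmin sits at the ceiling. The value function
    peaks near 105 Hz, the lowest grid frequency delivering ≥80% of the
    maximal rigidity benefit.
    """
    curve = RigidityCurve(
        r_off=1.2,
        dip10_amp=0.15,
        dip10_width=8.0,
        worsen_amp=0.15,
        worsen_center=35.0,
        worsen_width=12.0,
        benefit_amp=0.6,
        benefit_center=70.0,
        benefit_slope=25.0,
        bump_amp=0.0,
    )
    grid = np.arange(FREQ_MIN, 155.0 + 2.5, 5.0)
    noise_sd = 0.05 * float(np.ptp(curve(grid)))
    value_fn = ValueFunction(lambda_se=0.18, se_onset=100.0, se_slope=15.0, pref_noise=0.05)
    return VirtualPatient(curve, noise_sd, 155.0, value_fn, rng_seed, name="ar1")


def profile_ar2(rng_seed: int = 0) -> VirtualPatient:
    """Akinetic-rigid profile 2: ceiling 185 Hz with a 130–155 Hz rigidity bump."""
    curve = RigidityCurve(
        r_off=1.0,
        dip10_amp=0.12,
        dip10_width=8.0,
        worsen_amp=0.12,
        worsen_center=35.0,
        worsen_width=12.0,
        benefit_amp=0.5,
        benefit_center=80.0,
        benefit_slope=12.0,
        bump_amp=0.12,
        bump_center=142.5,
        bump_width=10.0,
    )
    grid = np.arange(FREQ_MIN, FREQ_MAX + 2.5, 5.0)
    noise_sd = 0.05 * float(np.ptp(curve(grid)))
    value_fn = ValueFunction(lambda_se=0.34, se_onset=95.0, se_slope=15.0, pref_noise=0.05)
    return VirtualPatient(curve, noise_sd, 185.0, value_fn, rng_seed, name="ar2")


_PROFILES = {"ar1": profile_ar1, "ar2": profile_ar2}


def get_profile(name: str, rng_seed: int = 0) -> VirtualPatient:
    """Shipped profile by name (``ar1`` or ``ar2``)."""
    if name not in _PROFILES:
        raise InvalidParameterError(f"unknown profile {name!r}; choose from {sorted(_PROFILES)}")
    return _PROFILES[name](rng_seed)


def save_patient(patient: VirtualPatient, path) -> None:
    with open(path, "w") as fh:
        json.dump(patient.to_dict(), fh, indent=2)


def load_patient(path) -> VirtualPatient:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format_version", PATIENT_FORMAT_VERSION) != PATIENT_FORMAT_VERSION:
        from .exceptions import UnsupportedVersionError

        raise UnsupportedVersionError(
            f"patient file format_version {d.get('format_version')} unsupported"
        )
    return VirtualPatient.from_dict(d)
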