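"""Rigidity quantification from manipulandum torque traces.

A robotic manipulandum imposes sinusoidal supination–pronation on the forearm
while a strain gauge records the resistive torque (nominally sampled at
1 kHz). Rigidity is summarised by a single scalar, the *RoMaR* value: the
torque is low-pass filtered (20 Hz, 2-pole Butterworth), rectified, and
integrated over time to give the angular impulse; the slope of the impulse
versus time over a fixed analysis window (20 s, after a 5 s warm-up) is the
RoMaR value, in units of N·m. A stiffer arm resists the imposed movement
with larger torque, a steeper impulse, and hence a larger RoMaR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .exceptions import InsufficientDataError, InvalidParameterError

__all__ = [
    "TorqueTrace",
    "RoMaRValue",
    "lowpass_filter",
    "compute_romar",
    "read_torque_csv",
    "write_romar_csv",
]


@dataclass
class TorqueTrace:
    """Raw or filtered torque versus time from one manipulandum trial.

    Parameters
    ----------
    t : array of float
        Sample times in seconds, strictly increasing on a uniform grid.
    torque : array of float
        Resistive torque in N·m, same length as ``t``.
    fs : float
        Sampling rate in Hz (nominally 1000).
    meta : dict
        Free-form trial annotations (stimulation frequency, participant,
        visit, ...). Carried through filtering unchanged.
    """

    t: np.ndarray
    torque: np.ndarray
    fs: float = 1000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.torque = np.asarray(self.torque, dtype=float)
        if self.t.ndim != 1 or self.torque.ndim != 1:
            raise InvalidParameterError("t and torque must be 1-D arrays")
        if self.t.size != self.torque.size:
            raise InvalidParameterError("t and torque must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise InvalidParameterError("t must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-9:
                raise InvalidParameterError("t must be uniformly spaced (within 1e-9 s)")
        if self.fs <= 0:
            raise InvalidParameterError("fs must be positive")

    @property
    def duration(self) -> float:
        """Trace duration in seconds (last minus first sample time)."""
        if self.t.size == 0:
            return 0.0
        return float(self.t[-1] - self.t[0])


@dataclass(frozen=True)
class RoMaRValue:
    """A single rigidity measurement.

    ``value`` is the ordinary-least-squares slope of the angular impulse
    (time integral of rectified torque) versus time over ``window`` seconds;
    ``fit_residual`` is the RMS residual of that linear fit, a diagnostic of
    how steadily the impulse accumulated.
    """

    value: float
    window: tuple[float, float]
    fit_residual: float


def lowpass_filter(
    trace: TorqueTrace,
    cutoff: float = 20.0,
    order: int = 2,
    zero_phase: bool = False,
) -> TorqueTrace:
    """Low-pass Butterworth filter of a torque trace.

    The default is the causal (forward-only) 2-pole filter at 20 Hz used for
    real-time rigidity estimation. ``zero_phase=True`` applies the same filter
    forward and backward (zero phase, squared magnitude response) for offline
    use.

    Raises
    ------
    InvalidParameterError
        If ``cutoff`` is at or above the Nyquist frequency.
    """
    nyquist = trace.fs / 2.0
    if cutoff <= 0 or cutoff >= nyquist:
        raise InvalidParameterError(
            f"cutoff must lie in (0, {nyquist}) Hz for fs={trace.fs} Hz"
        )
    if order < 1:
        raise InvalidParameterError("order must be >= 1")
    sos = sps.butter(order, cutoff, btype="low", fs=trace.fs, output="sos")
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, trace.torque)
    else:
        filtered = sps.sosfilt(sos, trace.torque)
    return TorqueTrace(trace.t.copy(), filtered, trace.fs, dict(trace.meta))


def compute_romar(
    trace: TorqueTrace,
    warmup: float = 5.0,
    window: float = 20.0,
    prefilter: bool = True,
    cutoff: float = 20.0,
    order: int = 2,
) -> RoMaRValue:
    """Compute the RoMaR rigidity value from one torque trace.

    Pipeline (order matters): low-pass filter (unless ``prefilter=False``,
    for traces already filtered), rectify, cumulative trapezoidal integral
    over the analysis window, OLS slope of the impulse against time.

    The first ``warmup`` seconds are discarded; the analysis window is the
    following ``window`` seconds. Traces longer than ``warmup + window`` are
    truncated, shorter ones rejected.

    Raises
    ------
    InsufficientDataError
        If the trace is shorter than ``warmup + window`` seconds or the
        window contains fewer than two samples.
    """
    if warmup < 0 or window <= 0:
        raise InvalidParameterError("warmup must be >= 0 and window > 0")
    if trace.duration + 1e-9 < warmup + window:
        raise InsufficientDataError(
            f"trace of {trace.duration:.3f} s is shorter than "
            f"warmup + window = {warmup + window:.3f} s"
        )
    work = lowpass_filter(trace, cutoff=cutoff, order=order) if prefilter else trace
    t0 = work.t[0]
    mask = (work.t - t0 >= warmup - 1e-12) & (work.t - t0 <= warmup + window + 1e-12)
    t_w = work.t[mask]
    torque_w = work.torque[mask]
    if t_w.size < 2:
        raise InsufficientDataError("analysis window contains fewer than two samples")
    if np.all(torque_w == 0.0):
        warnings.warn("all-zero torque in analysis window; RoMaR = 0", stacklevel=2)
        return RoMaRValue(0.0, (float(t_w[0]), float(t_w[-1])), 0.0)
    impulse = cumulative_trapezoid(np.abs(torque_w), t_w, initial=0.0)
    slope, intercept = np.polyfit(t_w, impulse, 1)
    resid = impulse - (slope * t_w + intercept)
    rms = float(np.sqrt(np.mean(resid**2)))
    return RoMaRValue(float(slope), (float(t_w[0]), float(t_w[-1])), rms)


def read_torque_csv(path, fs: float | None = None, meta: dict | None = None) -> TorqueTrace:
    """Read a torque trace from CSV with columns ``time_s, torque_nm``.

    Extra columns are ignored. If ``fs`` is omitted it is inferred from the
    median sample spacing.
    """
    df = pd.read_csv(path)
    missing = {"time_s", "torque_nm"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"torque CSV missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        if t.size < 2:
            raise InsufficientDataError("cannot infer fs from fewer than 2 samples")
        fs = 1.0 / float(np.median(np.diff(t)))
    return TorqueTrace(t, df["torque_nm"].to_numpy(dtype=float), fs, meta or {})


def write_romar_csv(results, path) -> None:
    """Write RoMaR results as CSV ``frequency_hz,romar,fit_residual``.

    ``results`` is an iterable of ``(frequency_hz, RoMaRValue)`` pairs.
    """
    rows = [
        {"frequency_hz": f, "romar": r.value, "fit_residual": r.fit_residual}
        for f, r in results
    ]
    pd.DataFrame(rows, columns=["frequency_hz", "romar", "fit_residual"]).to_csv(
        path, index=False
    )
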