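"""Post-hoc analysis: optimal frequency, the frequency-range metric, and the
sampling-efficiency comparison (equal-interval and random sampling versus
Bayesian optimization).

The *optimal frequency* is where the GP posterior mean is minimal. The
*frequency range* quantifies how sharply the model pins down that optimum:
all grid frequencies whose predicted rigidity lies within one posterior
standard deviation (taken at the minimum) above the minimum mean. Two
summaries are reported: the width of the contiguous interval containing the
optimum (the headline metric) and the distance from the optimum down to the
lowest in-range frequency (the alternative definition used when the optimum
sits at the top of the grid).

Efficiency simulations rebuild GP fits from subsets of a brute-force sweep:
``simulate_equal_interval`` picks n approximately evenly spaced tested
frequencies (rounded to the nearest tested 5 Hz setting, midpoints rounding
up), ``simulate_random`` draws n tested frequencies uniformly with
replacement over many seeded repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ObservationSet
from .exceptions import InvalidParameterError
from .gp import PredictiveDistribution, RigidityGP, RigidityGPResults
from .session import SessionState

__all__ = [
    "FrequencyRangeResult",
    "optimal_frequency",
    "frequency_range",
    "fit_observations",
    "simulate_equal_interval",
    "simulate_random",
    "bayesopt_progress",
    "efficiency_report",
    "plot_efficiency",
]


@dataclass(frozen=True)
class FrequencyRangeResult:
    """Frequency-range metric of one predictive distribution."""

    x_opt: float  # GP-mean argmin, Hz
    mu_min: float  # posterior mean at x_opt
    sigma_min: float  # posterior sd at x_opt
    range_set: np.ndarray  # all grid frequencies with mu <= mu_min + sigma_min
    interval: tuple[float, float]  # contiguous run containing x_opt
    width: float  # interval width, Hz
    lower_distance: float  # x_opt minus the interval's lower edge, Hz


def optimal_frequency(pred: PredictiveDistribution) -> float:
    """Grid frequency minimizing the posterior mean; ties to the lowest."""
    order = np.argsort(pred.grid)
    mu = pred.mu[order]
    return float(pred.grid[order][int(np.argmin(mu))])


def frequency_range(pred: PredictiveDistribution) -> FrequencyRangeResult:
    """Frequencies indistinguishable from the predicted minimum.

    Membership uses mu(x) <= mu_min + sigma_min (one-sided above the
    minimum). Both the full membership set and the contiguous interval
    containing the optimum are returned.
    """
    order = np.argsort(pred.grid)
    grid = pred.grid[order]
    mu = pred.mu[order]
    sigma = pred.sigma[order]
    i_opt = int(np.argmin(mu))
    mu_min = float(mu[i_opt])
    sigma_min = float(sigma[i_opt])
    member = mu <= mu_min + sigma_min + 1e-12
    lo = i_opt
    while lo > 0 and member[lo - 1]:
        lo -= 1
    hi = i_opt
    while hi < grid.size - 1 and member[hi + 1]:
        hi += 1
    return FrequencyRangeResult(
        x_opt=float(grid[i_opt]),
        mu_min=mu_min,
        sigma_min=sigma_min,
        range_set=grid[member],
        interval=(float(grid[lo]), float(grid[hi])),
        width=float(grid[hi] - grid[lo]),
        lower_distance=float(grid[i_opt] - grid[lo]),
    )


def fit_observations(
    x, y, seed: int = 0, mean_const: float | None = None, restarts: int = 8
) -> RigidityGPResults:
    """Standard GP fit used by every simulation (shared hyperparameter policy)."""
    return RigidityGP(x, y, mean_const=mean_const).fit(restarts=restarts, seed=seed)


def participant_params(bf: ObservationSet, seed: int = 0):
    """Participant-level kernel hyperparameters from the full sweep.

    The length-constant (and variances) are estimated once per participant
    from all of their brute-force data; the post-hoc subset simulations
    reuse them. Refitting hyperparameters inside every small subset would
    measure refit stability rather than sampling design, and tiny designs
    without repeated frequencies routinely produce degenerate refits.
    """
    return fit_observations(bf.x, bf.y, seed=seed).params


def _tested_values(bf: ObservationSet) -> tuple[np.ndarray, np.ndarray]:
    """Distinct tested frequencies and their (averaged) RoMaR values."""
    x = bf.x
    y = bf.y
    freqs = np.unique(x)
    vals = np.array([y[x == f].mean() for f in freqs])
    return freqs, vals


def _round_to_tested(target: float, tested: np.ndarray) -> float:
    """Nearest tested setting; midpoint ties round up."""
    dist = np.abs(tested - target)
    best = dist.min()
    candidates = tested[dist <= best + 1e-9]
    return float(candidates.max())


def select_equal_interval(bf: ObservationSet, n: int) -> np.ndarray:
    """The n approximately-evenly-spaced tested frequencies (10 Hz to max tolerated)."""
    if n < 2:
        raise InvalidParameterError("equal-interval selection needs n >= 2")
    tested, _ = _tested_values(bf)
    targets = np.linspace(tested.min(), tested.max(), n)
    return np.array([_round_to_tested(t, tested) for t in targets])


def simulate_equal_interval(
    bf: ObservationSet, n: int, seed: int = 0, grid=None, params=None
) -> FrequencyRangeResult:
    """Frequency range of a GP over n equally spaced brute-force values.

    The GP reuses the participant-level hyperparameters (fitted on the full
    sweep, see ``participant_params``) unless ``params`` is given.
    """
    tested, vals = _tested_values(bf)
    if params is None:
        params = participant_params(bf, seed=seed)
    sel = select_equal_interval(bf, n)
    y = np.array([vals[tested == f][0] for f in sel])
    model = RigidityGP(sel, y, mean_const=float(np.mean(y)))
    grid = tested if grid is None else np.asarray(grid, dtype=float)
    return frequency_range(model.predict(grid, params))


def simulate_random(
    bf: ObservationSet, n: int, reps: int = 50, rng=0, grid=None, params=None
) -> dict:
    """Random sampling baseline: mean/sd frequency-range width over seeded reps.

    Each repeat draws n tested frequencies uniformly with replacement (a
    repeat re-uses the recorded value) and evaluates the GP under the
    participant-level hyperparameters.
    """
    if n < 2:
        raise InvalidParameterError("random selection needs n >= 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tested, vals = _tested_values(bf)
    if params is None:
        params = participant_params(bf)
    grid = tested if grid is None else np.asarray(grid, dtype=float)
    widths = []
    results = []
    for rep in range(reps):
        sel = rng.choice(tested, size=n, replace=True)
        while np.unique(sel).size < 2:
            # a draw can land on a single frequency; re-draw from the same stream
            sel = rng.choice(tested, size=n, replace=True)
        y = np.array([vals[tested == f][0] for f in sel])
        model = RigidityGP(sel, y, mean_const=float(np.mean(y)))
        fr = frequency_range(model.predict(grid, params))
        widths.append(fr.width)
        results.append(fr)
    widths = np.asarray(widths)
    return {
        "mean_width": float(widths.mean()),
        "sd_width": float(widths.std(ddof=0)),
        "widths": widths,
        "results": results,
    }


def bayesopt_progress(state: SessionState, grid=None, min_n: int = 1) -> pd.DataFrame:
    """Frequency range after each prefix of the session history.

    Refits the GP (frozen seed-mean once available) on the first n
    observations for n = min_n .. len(history), one row per measurement.
    A single observation cannot identify hyperparameters, so the n = 1 row
    predicts with the parameters of the earliest identifiable fit (n = 2).
    """
    x, y = state.history.x, state.history.y
    n_seeds = len(state.config.seeds)
    if grid is None:
        grid = state.config.grid(state.ceiling)
    rows = []
    first_params = None
    for n in range(max(min_n, 2), len(x) + 1):
        mean_const = float(np.mean(y[:n_seeds])) if n >= n_seeds else None
        res = fit_observations(x[:n], y[:n], seed=n, mean_const=mean_const)
        if first_params is None:
            first_params = res.params
        fr = frequency_range(res.predict(grid))
        rows.append(
            {"method": "bayesopt", "n": n, "rep": 0, "width_hz": fr.width,
             "lower_distance_hz": fr.lower_distance, "x_opt_hz": fr.x_opt}
        )
    if min_n <= 1 and len(x) >= 2 and first_params is not None:
        gp1 = RigidityGP(x[:1], y[:1], mean_const=float(y[0]))
        fr = frequency_range(gp1.predict(grid, first_params))
        rows.insert(
            0,
            {"method": "bayesopt", "n": 1, "rep": 0, "width_hz": fr.width,
             "lower_distance_hz": fr.lower_distance, "x_opt_hz": fr.x_opt},
        )
    return pd.DataFrame(rows)


def efficiency_report(
    bf: ObservationSet | None = None,
    session: SessionState | None = None,
    n_values=None,
    reps: int = 50,
    rng_seed: int = 0,
    grid=None,
) -> pd.DataFrame:
    """Per-method, per-n frequency-range table (plot-ready, CSV-friendly).

    Columns: ``method, n, rep, width_hz, lower_distance_hz, x_opt_hz``; the
    random method contributes one row per repeat so mean ± sd can be formed
    downstream.
    """
    frames = []
    if bf is not None:
        tested, _ = _tested_values(bf)
        params = participant_params(bf)
        if n_values is None:
            n_values = list(range(2, tested.size + 1))
        rows = []
        for n in n_values:
            fr = simulate_equal_interval(bf, n, grid=grid, params=params)
            rows.append(
                {"method": "equal_interval", "n": n, "rep": 0, "width_hz": fr.width,
                 "lower_distance_hz": fr.lower_distance, "x_opt_hz": fr.x_opt}
            )
        frames.append(pd.DataFrame(rows))
        rng = np.random.default_rng(rng_seed)
        rows = []
        for n in n_values:
            sim = simulate_random(bf, n, reps=reps, rng=rng, grid=grid, params=params)
            for rep, fr in enumerate(sim["results"]):
                rows.append(
                    {"method": "random", "n": n, "rep": rep, "width_hz": fr.width,
                     "lower_distance_hz": fr.lower_distance, "x_opt_hz": fr.x_opt}
                )
        frames.append(pd.DataFrame(rows))
    if session is not None:
        frames.append(bayesopt_progress(session, grid=grid))
    if not frames:
        raise InvalidParameterError("need brute-force data and/or a session state")
    return pd.concat(frames, ignore_index=True)


def plot_efficiency(report: pd.DataFrame, ax=None):
    """Mean frequency-range width versus number of samples, per method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for method, df in report.groupby("method"):
        agg = df.groupby("n")["width_hz"].agg(["mean", "std"])
        ax.plot(agg.index, agg["mean"], marker="o", label=method)
        if (df["rep"] > 0).any():
            ax.fill_between(
                agg.index,
                agg["mean"] - agg["std"].fillna(0.0),
                agg["mean"] + agg["std"].fillna(0.0),
                alpha=0.2,
            )
    ax.set_xlabel("number of rigidity measurements")
    ax.set_ylabel("frequency-range width (Hz)")
    ax.legend()
    return ax
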