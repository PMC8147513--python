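"""Expected-improvement acquisition over a discrete frequency grid.

The session searches for the stimulation frequency minimizing rigidity, so
improvement at a candidate x is I(x) = f(x⁻) − μ(x), where the incumbent
f(x⁻) is the *minimum observed* RoMaR so far. Expected improvement under the
Gaussian posterior is

    u(x) = I(x)·Φ(Z) + σ(x)·φ(Z),  Z = I(x)/σ(x)   if σ(x) > 0,
    u(x) = 0                                        if σ(x) = 0,

with Φ and φ the standard normal CDF and PDF. Pure EI can over-exploit the
current minimum; an exploration rule with ratio 0.5 (see
``select_next_frequency``) diverts one step to the highest-variance grid
point when the EI argmax is already measured to well within the noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .exceptions import NoFeasibleFrequencyError
from .gp import PredictiveDistribution, RigidityGPResults

__all__ = ["AcquisitionResult", "expected_improvement", "select_next_frequency"]


def _phi(z):
    return np.exp(-0.5 * z**2) / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class AcquisitionResult:
    """Outcome of one acquisition step on a feasible grid."""

    grid: np.ndarray
    utility: np.ndarray
    x_next: float
    incumbent: float
    overexploit_flag: bool


def expected_improvement(pred: PredictiveDistribution, incumbent: float) -> np.ndarray:
    """Closed-form EI (minimization) at every grid point of ``pred``."""
    improve = incumbent - pred.mu
    sigma = pred.sigma
    u = np.zeros_like(sigma)
    pos = sigma > 0
    z = improve[pos] / sigma[pos]
    u[pos] = improve[pos] * ndtr(z) + sigma[pos] * _phi(z)
    return np.maximum(u, 0.0)


def select_next_frequency(
    results: RigidityGPResults,
    grid,
    ceiling: float | None = None,
    exploration_ratio: float = 0.5,
) -> AcquisitionResult:
    """Pick the next stimulation frequency to test.

    EI is evaluated on the grid restricted to the tolerability ceiling; the
    argmax wins, ties broken toward the lowest frequency (clinically
    conservative). If the posterior sd at the EI argmax is below
    ``exploration_ratio * sqrt(noise_var)`` — i.e. the model is re-sampling a
    point it already knows to well within measurement noise — the step is
    flagged as over-exploiting and the maximum-posterior-variance grid point
    is selected instead.

    With no observations the incumbent defaults to the prior mean, making the
    utility constant and the selection fall to the lowest feasible frequency.
    """
    grid = np.sort(np.asarray(grid, dtype=float).reshape(-1))
    if ceiling is not None:
        grid = grid[grid <= ceiling + 1e-9]
    if grid.size == 0:
        raise NoFeasibleFrequencyError("no candidate frequency at or below the ceiling")
    pred = results.predict(grid)
    if results.model.nobs:
        incumbent = float(np.min(results.model.y))
    else:
        incumbent = results.mean_const
    utility = expected_improvement(pred, incumbent)
    idx = int(np.argmax(utility))  # first max = lowest frequency on sorted grid
    overexploit = bool(
        pred.sigma[idx] < exploration_ratio * np.sqrt(results.params.noise_var)
    )
    if overexploit:
        idx = int(np.argmax(pred.sigma))
    return AcquisitionResult(grid, utility, float(grid[idx]), incumbent, overexploit)
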