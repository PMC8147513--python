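"""Gaussian-process regression of rigidity (RoMaR) on stimulation frequency.

The model is a constant-mean GP with a Matérn covariance,

    y_i = m + f(x_i) + eps_i,   f ~ GP(0, k),   eps_i ~ N(0, noise_var),

where x is stimulation frequency in Hz and y the measured RoMaR value. The
constant mean ``m`` is fixed from data (in the optimization protocol, the
arithmetic mean of the four seed measurements) rather than learned; the
kernel hyperparameters (length-constant, signal variance, noise variance)
are fitted by maximizing the log marginal likelihood with a seeded
multi-start quasi-Newton search on log-parameters.

Usage follows the model/results convention::

    model = RigidityGP(x, y)
    res = model.fit(seed=0)
    pred = res.predict(np.arange(10, 160, 5))
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .exceptions import DegenerateDesignError, InsufficientDataError, NumericalError
from .kernels import KernelParams, kernel_matrix

__all__ = [
    "PredictiveDistribution",
    "RigidityGP",
    "RigidityGPResults",
    "fit_hyperparameters",
    "gp_predict",
]

_JITTER_START = 1e-10
_JITTER_MAX = 1e-4
_FIELDS = ("ell", "signal_var", "noise_var")


@dataclass(frozen=True)
class PredictiveDistribution:
    """Posterior mean and standard deviation on a frequency grid."""

    grid: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))


def _chol_with_jitter(K: np.ndarray, scale: float):
    """Cholesky factorization, escalating diagonal jitter only on failure.

    Tries no jitter first so that noise-free interpolation stays exact,
    then scale*1e-10 escalating tenfold up to scale*1e-4.
    """
    jitters = [0.0] + list(scale * _JITTER_START * 10.0 ** np.arange(0, 7))
    for j in jitters:
        if j > scale * _JITTER_MAX * (1 + 1e-12):
            break
        try:
            return cho_factor(K + j * np.eye(K.shape[0]), lower=True), j
        except np.linalg.LinAlgError:
            continue
    raise NumericalError("covariance not positive definite after jitter escalation")


class RigidityGP:
    """GP model of RoMaR versus stimulation frequency.

    Parameters
    ----------
    x, y : arrays
        Observed stimulation frequencies (Hz) and RoMaR values. May be
        empty, in which case only prior prediction is available.
    mean_const : float, optional
        Constant prior mean. Defaults to ``mean(y)`` (or 0 with no data).
        In the session protocol this is frozen to the mean of the four seed
        measurements.
    nu : float
        Matérn order, fixed at 3/2 by default.
    """

    def __init__(self, x, y, mean_const: float | None = None, nu: float = 1.5):
        self.x = np.asarray(x, dtype=float).reshape(-1)
        self.y = np.asarray(y, dtype=float).reshape(-1)
        if self.x.size != self.y.size:
            raise InsufficientDataError("x and y must have equal length")
        if mean_const is None:
            mean_const = float(np.mean(self.y)) if self.y.size else 0.0
        self.mean_const = float(mean_const)
        self.nu = float(nu)

    @property
    def nobs(self) -> int:
        return self.x.size

    def loglike(self, params: KernelParams) -> float:
        """Log marginal likelihood of the observations under ``params``."""
        n = self.nobs
        if n == 0:
            return 0.0
        K = kernel_matrix(self.x, self.x, params) + params.noise_var * np.eye(n)
        cf, _ = _chol_with_jitter(K, params.signal_var)
        r = self.y - self.mean_const
        alpha = cho_solve(cf, r)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return float(-0.5 * r @ alpha - 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi))

    def _default_bounds(self) -> dict:
        # noise sd is floored at 1% of the data sd: without repeated
        # measurements the marginal likelihood otherwise collapses the noise
        # to zero and interpolates it, which corrupts every derived metric
        vy = float(np.var(self.y)) if self.nobs else 1.0
        vy = max(vy, 1e-12)
        return {
            "ell": (2.5, 350.0),
            "signal_var": (1e-3 * vy, 1e3 * vy),
            "noise_var": (1e-4 * vy, 10.0 * vy),
        }

    def fit(
        self,
        fixed: dict | None = None,
        bounds: dict | None = None,
        restarts: int = 8,
        seed: int = 0,
    ) -> "RigidityGPResults":
        """Fit kernel hyperparameters by maximum marginal likelihood.

        Parameters
        ----------
        fixed : dict, optional
            Values to hold fixed, keyed by ``ell``/``signal_var``/``noise_var``.
        bounds : dict, optional
            Per-field ``(lo, hi)`` search intervals overriding the defaults
            (ell in [2.5, 350] Hz; noise_var in [1e-6, 10] x var(y)).
        restarts : int
            Number of multi-start initializations (first is a data-driven
            heuristic, the rest log-uniform over the bounds).
        seed : int
            Seed for the restart draws; the fit is deterministic given
            data, bounds and seed.
        """
        fixed = dict(fixed or {})
        free = [f for f in _FIELDS if f not in fixed]
        if free and np.unique(self.x).size < 2:
            raise DegenerateDesignError(
                "hyperparameter fitting needs observations at >= 2 distinct frequencies"
            )
        all_bounds = self._default_bounds()
        all_bounds.update(bounds or {})

        def make_params(values: dict) -> KernelParams:
            merged = {**values, **fixed}
            return KernelParams(nu=self.nu, **merged)

        if not free:
            params = make_params({})
            return RigidityGPResults(self, params, self.loglike(params))

        lo = np.log([all_bounds[f][0] for f in free])
        hi = np.log([all_bounds[f][1] for f in free])

        def nll(theta: np.ndarray) -> float:
            values = {f: float(np.exp(v)) for f, v in zip(free, theta)}
            try:
                return -self.loglike(make_params(values))
            except NumericalError:
                return 1e12

        vy = max(float(np.var(self.y)), 1e-12)
        span = float(np.ptp(self.x)) or 10.0
        heuristic = {"ell": span / 3.0, "signal_var": vy, "noise_var": 0.1 * vy}
        starts = [
            np.clip(np.log([heuristic[f] for f in free]), lo, hi)
        ]
        rng = np.random.default_rng(seed)
        for _ in range(max(0, restarts - 1)):
            starts.append(rng.uniform(lo, hi))

        best = None
        for theta0 in starts:
            res = optimize.minimize(
                nll, theta0, method="L-BFGS-B", bounds=list(zip(lo, hi))
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        values = {f: float(np.exp(v)) for f, v in zip(free, best.x)}
        params = make_params(values)
        return RigidityGPResults(self, params, float(-best.fun))

    def predict(self, grid, params: KernelParams) -> PredictiveDistribution:
        """Predictive distribution on ``grid`` under fixed hyperparameters.

        mu(x)     = m + k^T (K + noise_var I)^-1 (y - m)
        sigma²(x) = k(x, x) - k^T (K + noise_var I)^-1 k   (floored at 0)

        With no observations this returns the prior: mu = m,
        sigma = sqrt(signal_var).
        """
        grid = np.asarray(grid, dtype=float).reshape(-1)
        if self.nobs == 0:
            mu = np.full(grid.shape, self.mean_const)
            sigma = np.full(grid.shape, np.sqrt(params.signal_var))
            return PredictiveDistribution(grid, mu, sigma)
        n = self.nobs
        K = kernel_matrix(self.x, self.x, params) + params.noise_var * np.eye(n)
        cf, _ = _chol_with_jitter(K, params.signal_var)
        ks = kernel_matrix(grid, self.x, params)  # (g, n)
        alpha = cho_solve(cf, self.y - self.mean_const)
        mu = self.mean_const + ks @ alpha
        v = cho_solve(cf, ks.T)  # (n, g)
        var = params.signal_var - np.einsum("gn,ng->g", ks, v)
        sigma = np.sqrt(np.maximum(var, 0.0))
        return PredictiveDistribution(grid, mu, sigma)


class RigidityGPResults:
    """Fitted rigidity GP: hyperparameters, fit quality, prediction, summary."""

    def __init__(self, model: RigidityGP, params: KernelParams, llf: float):
        self.model = model
        self.params = params
        self.llf = float(llf)

    @property
    def mean_const(self) -> float:
        return self.model.mean_const

    def predict(self, grid) -> PredictiveDistribution:
        return self.model.predict(grid, self.params)

    def to_dict(self) -> dict:
        return {
            "nu": self.params.nu,
            "ell": self.params.ell,
            "signal_var": self.params.signal_var,
            "noise_var": self.params.noise_var,
            "mean_const": self.mean_const,
            "llf": self.llf,
        }

    def summary(self) -> str:
        lines = [
            "Rigidity GP (Matérn) regression results",
            "=" * 43,
            f"{'No. observations':<26}{self.model.nobs:>17d}",
            f"{'Log marginal likelihood':<26}{self.llf:>17.4f}",
            f"{'Matérn order nu':<26}{self.params.nu:>17.3g}",
            f"{'Length-constant ell (Hz)':<26}{self.params.ell:>17.4f}",
            f"{'Signal variance':<26}{self.params.signal_var:>17.6g}",
            f"{'Noise variance':<26}{self.params.noise_var:>17.6g}",
            f"{'Constant mean (RoMaR)':<26}{self.mean_const:>17.6g}",
            "=" * 43,
        ]
        return "\n".join(lines)

    def plot(self, grid=None, ax=None):
        """Plot the posterior mean ± 1 sd band with the observations."""
        import matplotlib.pyplot as plt

        if grid is None:
            lo = self.model.x.min() if self.model.nobs else 10.0
            hi = self.model.x.max() if self.model.nobs else 185.0
            grid = np.linspace(lo, hi, 200)
        pred = self.predict(grid)
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(
            pred.grid, pred.mu - pred.sigma, pred.mu + pred.sigma, alpha=0.3,
            label="±1 sd",
        )
        ax.plot(pred.grid, pred.mu, label="posterior mean")
        if self.model.nobs:
            ax.plot(self.model.x, self.model.y, "k.", label="observations")
        ax.set_xlabel("stimulation frequency (Hz)")
        ax.set_ylabel("RoMaR (N·m)")
        ax.legend()
        return ax


def fit_hyperparameters(
    x,
    y,
    mean_const: float | None = None,
    fixed: dict | None = None,
    bounds: dict | None = None,
    restarts: int = 8,
    seed: int = 0,
) -> KernelParams:
    """Functional wrapper: maximum-marginal-likelihood kernel parameters."""
    return RigidityGP(x, y, mean_const=mean_const).fit(
        fixed=fixed, bounds=bounds, restarts=restarts, seed=seed
    ).params


def gp_predict(x, y, params: KernelParams, grid, mean_const: float | None = None):
    """Functional wrapper: predictive distribution for data + hyperparameters."""
    return RigidityGP(x, y, mean_const=mean_const).predict(grid, params)
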