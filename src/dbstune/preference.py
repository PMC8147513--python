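"""Probit Gaussian-process preference model from pairwise comparisons.

A patient's value for a stimulation setting is modelled as v(x) = f(x) + eps
with f ~ GP(0, k) latent and eps ~ N(0, sigma_noise²) choice noise
(sigma_noise fixed at 1, not learned). Only binary comparisons are observed:
a dataset D = {a_i ≻ b_i} of "preferred a over b" records, each with probit
likelihood

    P(a ≻ b | f) = Φ( (f(a) − f(b)) / (√2·sigma_noise) ).

The latent values at the m distinct compared frequencies are estimated by
MAP: maximize  −½ fᵀK⁻¹f + Σ_i log Φ(Z_i)  by damped Newton–Raphson with
random restarts (the objective is concave, restarts guard the line search).
The likelihood only identifies f up to an additive constant, so the stored
f_MAP is centered to mean zero. The predictive distribution at new
frequencies uses

    mu(x)     = kᵀ K⁻¹ f_MAP
    sigma²(x) = k(x, x) − kᵀ (K + C⁻¹)⁻¹ k

where C is the Hessian of the negative log-likelihood at f_MAP (jittered
before inversion when comparisons leave it singular).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .exceptions import ConvergenceError, InsufficientDataError, InvalidParameterError
from .gp import PredictiveDistribution, _chol_with_jitter
from .kernels import KernelParams, kernel_matrix

__all__ = [
    "PreferencePair",
    "PreferenceDataset",
    "preference_probability",
    "PreferenceGP",
    "PreferenceGPResults",
    "fit_pgp_map",
    "pgp_predict",
    "preferred_frequency",
]


@dataclass(frozen=True)
class PreferencePair:
    """One pairwise choice: frequency ``a`` was preferred over ``b``.

    ``a == b`` is permitted — it arises when the optimizer re-tests the
    setting it just measured and the patient is still asked the
    current-versus-previous question. Such a pair carries no likelihood
    information (its probit argument is identically zero) but is kept so
    that a full session always records one choice per measurement after
    the first.
    """

    a: float
    b: float
    step_index: int = 0


@dataclass
class PreferenceDataset:
    """Ordered collection of preference pairs with CSV round-trip."""

    pairs: list[PreferencePair] = field(default_factory=list)

    def append(self, pair: PreferencePair) -> None:
        self.pairs.append(pair)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def frequencies(self) -> np.ndarray:
        """Sorted distinct frequencies appearing in any comparison."""
        vals = [p.a for p in self.pairs] + [p.b for p in self.pairs]
        return np.unique(np.asarray(vals, dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        # winner column follows the CSV convention: 'a' means frequency_a_hz won
        return pd.DataFrame(
            {
                "step_index": [p.step_index for p in self.pairs],
                "frequency_a_hz": [p.a for p in self.pairs],
                "frequency_b_hz": [p.b for p in self.pairs],
                "winner": ["a"] * len(self.pairs),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PreferenceDataset":
        needed = {"frequency_a_hz", "frequency_b_hz", "winner"}
        missing = needed - set(df.columns)
        if missing:
            raise InvalidParameterError(f"preferences missing columns: {sorted(missing)}")
        pairs = []
        for i, row in enumerate(df.itertuples(index=False)):
            winner = str(row.winner)
            if winner not in ("a", "b"):
                raise InvalidParameterError(f"winner must be 'a' or 'b', got {winner!r}")
            fa, fb = float(row.frequency_a_hz), float(row.frequency_b_hz)
            if winner == "b":
                fa, fb = fb, fa
            pairs.append(PreferencePair(fa, fb, int(getattr(row, "step_index", i))))
        return cls(pairs)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PreferenceDataset":
        return cls.from_dataframe(pd.read_csv(path))


def preference_probability(fa, fb, sigma_noise: float = 1.0):
    """Probit probability that the setting with latent value ``fa`` is preferred."""
    return ndtr((np.asarray(fa, dtype=float) - fb) / (np.sqrt(2.0) * sigma_noise))


class PreferenceGP:
    """Probit-GP preference model over the compared frequencies.

    Parameters
    ----------
    pairs : PreferenceDataset or iterable of PreferencePair
        Pairwise choices; at least one required.
    kernel : KernelParams
        GP prior covariance over frequency. By convention signal_var = 1 and
        the length-constant is borrowed from the same session's rigidity GP
        (binary choices alone do not identify it).
    sigma_noise : float
        Choice-noise scale in the probit likelihood; fixed, not learned.
    """

    def __init__(self, pairs, kernel: KernelParams, sigma_noise: float = 1.0):
        if not isinstance(pairs, PreferenceDataset):
            pairs = PreferenceDataset(list(pairs))
        if len(pairs) < 1:
            raise InsufficientDataError("at least one preference pair is required")
        self.pairs = pairs
        self.kernel = kernel
        self.sigma_noise = float(sigma_noise)
        self.x_train = pairs.frequencies
        index = {f: i for i, f in enumerate(self.x_train)}
        self._ia = np.array([index[p.a] for p in pairs], dtype=int)
        self._ib = np.array([index[p.b] for p in pairs], dtype=int)
        self._K = kernel_matrix(self.x_train, self.x_train, kernel)
        self._cf, _ = _chol_with_jitter(self._K, kernel.signal_var)

    @property
    def m(self) -> int:
        return self.x_train.size

    def _z(self, f: np.ndarray) -> np.ndarray:
        return (f[self._ia] - f[self._ib]) / (np.sqrt(2.0) * self.sigma_noise)

    def log_posterior(self, f: np.ndarray) -> float:
        """Unnormalized log posterior: GP prior + probit likelihood."""
        f = np.asarray(f, dtype=float)
        prior = -0.5 * f @ cho_solve(self._cf, f)
        return float(prior + np.sum(log_ndtr(self._z(f))))

    def _grad_hess_ll(self, f: np.ndarray):
        """Gradient of the log-likelihood and the C matrix (−Hessian)."""
        z = self._z(f)
        ratio = np.exp(norm.logpdf(z) - log_ndtr(z))  # φ(z)/Φ(z), stable
        s = np.sqrt(2.0) * self.sigma_noise
        g = np.zeros(self.m)
        np.add.at(g, self._ia, ratio / s)
        np.add.at(g, self._ib, -ratio / s)
        # -d²/dz² log Φ(z) = z·ratio + ratio²  (positive), scaled by 1/(2σ²)
        w = (z * ratio + ratio**2) / (s**2)
        C = np.zeros((self.m, self.m))
        np.add.at(C, (self._ia, self._ia), w)
        np.add.at(C, (self._ib, self._ib), w)
        np.add.at(C, (self._ia, self._ib), -w)
        np.add.at(C, (self._ib, self._ia), -w)
        return g, C

    def _newton(self, f0: np.ndarray, tol: float, maxiter: int):
        """Damped Newton ascent from ``f0``; returns (f, converged)."""
        f = f0.copy()
        obj = self.log_posterior(f)
        for _ in range(maxiter):
            g_ll, C = self._grad_hess_ll(f)
            grad = -cho_solve(self._cf, f) + g_ll
            if np.linalg.norm(grad) < tol:
                return f, True
            Kinv = cho_solve(self._cf, np.eye(self.m))
            H = Kinv + C  # negative Hessian of the log posterior (PD)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            t = 1.0
            for _ in range(40):  # step-halving line search
                cand = f + t * step
                cand_obj = self.log_posterior(cand)
                if cand_obj >= obj:
                    break
                t *= 0.5
            else:
                return f, False
            f, obj = cand, cand_obj
        g_ll, _ = self._grad_hess_ll(f)
        grad = -cho_solve(self._cf, f) + g_ll
        return f, bool(np.linalg.norm(grad) < tol)

    def fit(
        self,
        restarts: int = 25,
        seed: int = 0,
        tol: float = 1e-8,
        maxiter: int = 200,
    ) -> "PreferenceGPResults":
        """MAP estimate by Newton–Raphson with seeded random restarts.

        Initial conditions are drawn uniformly on [−1, 1] per coordinate;
        the best converged objective wins (ties to the lowest restart
        index). Raises ``ConvergenceError`` if no restart converges.
        """
        rng = np.random.default_rng(seed)
        best_f, best_obj = None, -np.inf
        best_any = -np.inf  # best objective seen, converged or not
        for _ in range(max(1, restarts)):
            f0 = rng.uniform(-1.0, 1.0, size=self.m)
            f, ok = self._newton(f0, tol, maxiter)
            obj = self.log_posterior(f)
            best_any = max(best_any, obj)
            if ok and obj > best_obj + 1e-12:
                best_f, best_obj = f, obj
        if best_f is None:
            raise ConvergenceError(
                "Newton-Raphson failed to converge from every restart",
                best_objective=best_any,
            )
        f_map = best_f - np.mean(best_f)  # identifiable only up to a constant
        _, C = self._grad_hess_ll(f_map)
        return PreferenceGPResults(self, f_map, C, self.log_posterior(f_map))


class PreferenceGPResults:
    """MAP-fitted preference model: latent values, prediction, summary."""

    def __init__(self, model: PreferenceGP, f_map, C, map_log_posterior: float):
        self.model = model
        self.f_map = np.asarray(f_map, dtype=float)
        self.C = np.asarray(C, dtype=float)
        self.map_log_posterior = float(map_log_posterior)

    @property
    def x_train(self) -> np.ndarray:
        return self.model.x_train

    def predict(self, grid) -> PredictiveDistribution:
        """Predictive latent-value distribution on ``grid``.

        C is given a 1e-8 diagonal jitter before inversion (escalating
        through the shared policy) since chain comparisons can leave it
        singular.
        """
        grid = np.asarray(grid, dtype=float).reshape(-1)
        m = self.model.m
        K, cf = self.model._K, self.model._cf
        ks = kernel_matrix(grid, self.x_train, self.model.kernel)  # (g, m)
        mu = ks @ cho_solve(cf, self.f_map)
        C_cf, _ = _chol_with_jitter(self.C + 1e-8 * np.eye(m), 1.0)
        Cinv = cho_solve(C_cf, np.eye(m))
        M_cf, _ = _chol_with_jitter(K + Cinv, self.model.kernel.signal_var)
        v = cho_solve(M_cf, ks.T)  # (m, g)
        prior_var = np.asarray(
            [self.model.kernel.signal_var] * grid.size, dtype=float
        )
        var = prior_var - np.einsum("gm,mg->g", ks, v)
        sigma = np.sqrt(np.maximum(var, 0.0))
        return PredictiveDistribution(grid, mu, sigma)

    def preferred_frequency(self, grid) -> float:
        """Peak of the predictive preference mean; ties to the lowest frequency."""
        return preferred_frequency(self.predict(grid))

    def to_dict(self) -> dict:
        return {
            "x_train": self.x_train.tolist(),
            "f_map": self.f_map.tolist(),
            "sigma_noise": self.model.sigma_noise,
            "kernel": {
                "nu": self.model.kernel.nu,
                "ell": self.model.kernel.ell,
                "signal_var": self.model.kernel.signal_var,
                "noise_var": self.model.kernel.noise_var,
            },
            "C": self.C.tolist(),
            "map_log_posterior": self.map_log_posterior,
        }

    def summary(self) -> str:
        lines = [
            "Probit-GP preference model (MAP)",
            "=" * 46,
            f"{'No. comparisons':<28}{len(self.model.pairs):>15d}",
            f"{'No. compared frequencies':<28}{self.model.m:>15d}",
            f"{'MAP log posterior':<28}{self.map_log_posterior:>15.4f}",
            f"{'Choice-noise scale sigma':<28}{self.model.sigma_noise:>15.3g}",
            f"{'Kernel ell (Hz)':<28}{self.model.kernel.ell:>15.4f}",
            "-" * 46,
            f"{'frequency (Hz)':>16}{'latent value':>18}",
        ]
        for f, v in zip(self.x_train, self.f_map):
            lines.append(f"{f:>16.1f}{v:>18.5f}")
        lines.append("=" * 46)
        return "\n".join(lines)

    def plot(self, grid=None, ax=None):
        """Plot the latent preference mean ± 1 sd over frequency."""
        import matplotlib.pyplot as plt

        if grid is None:
            grid = np.linspace(self.x_train.min(), self.x_train.max(), 200)
        pred = self.predict(grid)
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(pred.grid, pred.mu - pred.sigma, pred.mu + pred.sigma, alpha=0.3)
        ax.plot(pred.grid, pred.mu, label="latent preference mean")
        ax.plot(self.x_train, self.f_map, "k.", label="f_MAP")
        ax.set_xlabel("stimulation frequency (Hz)")
        ax.set_ylabel("latent value")
        ax.legend()
        return ax


def fit_pgp_map(
    pairs,
    kernel: KernelParams,
    restarts: int = 25,
    seed: int = 0,
    sigma_noise: float = 1.0,
) -> PreferenceGPResults:
    """Functional wrapper: MAP fit of the probit-GP preference model."""
    return PreferenceGP(pairs, kernel, sigma_noise=sigma_noise).fit(
        restarts=restarts, seed=seed
    )


def pgp_predict(results: PreferenceGPResults, grid) -> PredictiveDistribution:
    """Functional wrapper: predictive distribution of a fitted preference model."""
    return results.predict(grid)


def preferred_frequency(pred: PredictiveDistribution) -> float:
    """Argmax of the predictive mean; ties broken toward the lowest frequency."""
    order = np.argsort(pred.grid)
    mu = pred.mu[order]
    return float(pred.grid[order][int(np.argmax(mu))])
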