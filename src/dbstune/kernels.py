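"""Matérn covariance functions over stimulation frequency.

The Matérn family is parameterized by an order nu controlling sample-path
smoothness (nu = 3/2 gives once-differentiable paths — coarse data, smooth
trend), a length-constant ``ell`` in Hz setting how quickly the correlation
between two frequencies decays, and an output variance ``signal_var`` in
RoMaR² units. ``noise_var`` is the i.i.d. observation-noise variance added
to the kernel's diagonal when forming the training covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gamma as gamma_fn
from scipy.special import kv

from .exceptions import InvalidParameterError

__all__ = ["KernelParams", "matern_kernel", "kernel_matrix"]


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of a Matérn kernel plus observation noise.

    Attributes
    ----------
    nu : float
        Matérn order; 3/2 throughout this package.
    ell : float
        Length-constant in Hz (> 0).
    signal_var : float
        Kernel output variance, RoMaR² (> 0).
    noise_var : float
        Observation noise variance, RoMaR² (>= 0).
    """

    nu: float = 1.5
    ell: float = 30.0
    signal_var: float = 1.0
    noise_var: float = 0.0

    def __post_init__(self):
        if not (self.nu > 0):
            raise InvalidParameterError("nu must be > 0")
        if not (self.ell > 0):
            raise InvalidParameterError("ell must be > 0")
        if not (self.signal_var > 0):
            raise InvalidParameterError("signal_var must be > 0")
        if self.noise_var < 0:
            raise InvalidParameterError("noise_var must be >= 0")

    def replace(self, **kwargs) -> "KernelParams":
        return replace(self, **kwargs)


def matern_kernel(xi, xj, params: KernelParams):
    """Matérn covariance k(xi, xj); broadcasts over array inputs.

    For nu = 1/2, 3/2, 5/2 the closed forms are used; any other nu falls
    back to the general form

        k(r) = signal_var * 2^(1-nu)/Gamma(nu) * s^nu * K_nu(s),
        s = sqrt(2 nu) * r / ell,

    with K_nu the modified Bessel function of the second kind. k(x, x) equals
    ``signal_var`` exactly (the r -> 0 limit).
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    r = np.abs(xi - xj)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    sv, ell, nu = params.signal_var, params.ell, params.nu

    if nu == 0.5:
        k = sv * np.exp(-r / ell)
    elif nu == 1.5:
        s = np.sqrt(3.0) * r / ell
        k = sv * (1.0 + s) * np.exp(-s)
    elif nu == 2.5:
        s = np.sqrt(5.0) * r / ell
        k = sv * (1.0 + s + s**2 / 3.0) * np.exp(-s)
    else:
        s = np.sqrt(2.0 * nu) * r / ell
        k = np.full_like(s, sv)
        pos = s > 0
        sp = s[pos]
        k[pos] = sv * (2.0 ** (1.0 - nu) / gamma_fn(nu)) * sp**nu * kv(nu, sp)
    if scalar:
        return float(k.reshape(-1)[0])
    return k


def kernel_matrix(x1, x2, params: KernelParams) -> np.ndarray:
    """Dense covariance matrix K[i, j] = k(x1[i], x2[j])."""
    x1 = np.asarray(x1, dtype=float).reshape(-1, 1)
    x2 = np.asarray(x2, dtype=float).reshape(1, -1)
    return np.asarray(matern_kernel(x1, x2, params))
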