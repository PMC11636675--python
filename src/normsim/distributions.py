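"""Conditional response families used by the normative-model fitters.

Two four-parameter continuous families are provided, each defined as a
transformation of a standard reference distribution:

* **SHASH** (sinh-arcsinh, Jones & Pewsey form): if ``r = (y - location)/scale``
  then ``z = sinh(tail * asinh(r) - skew)`` is standard normal.  ``skew = 0``
  and ``tail = 1`` recover a Gaussian with mean ``location`` and standard
  deviation ``scale`` exactly.

* **BCT** (Box-Cox t, Rigby & Stasinopoulos parameterisation): for ``y > 0``,
  ``z = ((y/location)**power - 1) / (power * scale)`` (or
  ``log(y/location)/scale`` when ``power = 0``) follows a t distribution with
  ``dof`` degrees of freedom, truncated so that the support respects
  ``y > 0`` (the truncation mass is renormalised; for realistic parameters
  it is negligible).  ``location`` is the median; ``scale`` is relative
  (approximately the coefficient of variation).

All densities are computed on the log scale from closed-form expressions —
never by differencing cdfs — so they remain finite far into the tails.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats

__all__ = [
    "ShashParams",
    "BctParams",
    "shash_cdf",
    "shash_quantile",
    "shash_logpdf",
    "bct_cdf",
    "bct_quantile",
    "bct_logpdf",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class InvalidParameterError(ValueError):
    """Raised when a distribution parameter violates its constraints."""


@dataclasses.dataclass(frozen=True)
class ShashParams:
    """Parameters of the sinh-arcsinh family.

    location : real, same units as the response.
    scale : positive real, same units as the response.
    skew : real; 0 gives a symmetric distribution, positive skews right.
    tail : positive real; 1 gives Gaussian tails, smaller is heavier.
    """

    location: float
    scale: float
    skew: float = 0.0
    tail: float = 1.0

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise InvalidParameterError(f"scale must be > 0, got {self.scale}")
        if not (self.tail > 0):
            raise InvalidParameterError(f"tail must be > 0, got {self.tail}")


@dataclasses.dataclass(frozen=True)
class BctParams:
    """Parameters of the Box-Cox t family (positive response).

    location : positive real; the median of the distribution.
    scale : positive real; relative scale (approximate coefficient of variation).
    power : real; Box-Cox exponent (1 = no transformation, 0 = log).
    dof : positive real; degrees of freedom of the reference t distribution.
    """

    location: float
    scale: float
    power: float = 1.0
    dof: float = 10.0

    def __post_init__(self) -> None:
        if not (self.location > 0):
            raise InvalidParameterError(f"location must be > 0, got {self.location}")
        if not (self.scale > 0):
            raise InvalidParameterError(f"scale must be > 0, got {self.scale}")
        if not (self.dof > 0):
            raise InvalidParameterError(f"dof must be > 0, got {self.dof}")


# ---------------------------------------------------------------------------
# SHASH — array kernels (used directly by the fitters) and public wrappers.
# ---------------------------------------------------------------------------

def _shash_z(y, mu, sigma, nu, tau):
    r = (np.asarray(y, dtype=float) - mu) / sigma
    return np.sinh(tau * np.arcsinh(r) - nu)


def shash_cdf(y, params: ShashParams):
    """Cumulative probability of the SHASH distribution at ``y``."""
    z = _shash_z(y, params.location, params.scale, params.skew, params.tail)
    return stats.norm.cdf(z)


def shash_quantile(p, params: ShashParams):
    """Quantile (inverse cdf) of the SHASH distribution.

    Exact inverse of :func:`shash_cdf`:
    ``y = location + scale * sinh((asinh(z_p) + skew)/tail)`` with
    ``z_p`` the standard normal quantile of ``p``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p must lie strictly within (0, 1)")
    z = stats.norm.ppf(p)
    r = np.sinh((np.arcsinh(z) + params.skew) / params.tail)
    return params.location + params.scale * r


def _shash_logpdf_arrays(y, mu, sigma, nu, tau):
    """Vectorised SHASH log density; parameters may be arrays broadcast to y.

    With u = tau*asinh(r) - nu, z = sinh(u), cosh(u) = sqrt(1+z^2):
    log f = -log(sqrt(2*pi)) - z^2/2 + log(tau) - log(sigma)
            + log(cosh(u)) - log(1+r^2)/2
    log(cosh(u)) is evaluated as |u| + log1p(exp(-2|u|)) - log 2 for stability.
    """
    r = (np.asarray(y, dtype=float) - mu) / sigma
    a = np.arcsinh(r)
    u = tau * a - nu
    z = np.sinh(u)
    abs_u = np.abs(u)
    log_cosh_u = abs_u + np.log1p(np.exp(-2.0 * abs_u)) - math.log(2.0)
    return (
        -_LOG_SQRT_2PI
        - 0.5 * z * z
        + np.log(tau)
        - np.log(sigma)
        + log_cosh_u
        - 0.5 * np.log1p(r * r)
    )


def _shash_score_arrays(y, mu, sigma, nu, tau):
    """Per-observation derivatives of the SHASH log density.

    Returns (d/dmu, d/dlog(sigma), d/dnu, d/dlog(tau)) — the log links on the
    positive parameters match the links the fitter uses.
    """
    y = np.asarray(y, dtype=float)
    r = (y - mu) / sigma
    s2 = 1.0 + r * r
    s = np.sqrt(s2)
    a = np.arcsinh(r)
    u = tau * a - nu
    z = np.sinh(u)
    c = np.cosh(u)
    # dll/du = -z*cosh(u) + tanh(u)
    dll_du = -z * c + z / c
    # dll/dr at constant u-parameters
    dll_dr = dll_du * tau / s - r / s2
    d_mu = -dll_dr / sigma
    d_logsigma = -r * dll_dr - 1.0
    d_nu = -dll_du
    d_logtau = (dll_du * a + 1.0 / tau) * tau
    return d_mu, d_logsigma, d_nu, d_logtau


def shash_logpdf(y, params: ShashParams):
    """Log density of the SHASH distribution at ``y``."""
    return _shash_logpdf_arrays(
        y, params.location, params.scale, params.skew, params.tail
    )


# ---------------------------------------------------------------------------
# BCT
# ---------------------------------------------------------------------------

def _bct_z(y, mu, sigma, nu):
    y = np.asarray(y, dtype=float)
    nu_arr = np.asarray(nu, dtype=float)
    ratio = y / mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z_pow = (np.power(ratio, nu_arr) - 1.0) / (nu_arr * sigma)
        z_log = np.log(ratio) / sigma
    return np.where(nu_arr == 0.0, z_log, z_pow)


def _bct_trunc(sigma, nu, dof):
    """(lower-tail mass removed, renormalising mass) of the t truncation.

    For power > 0 the support maps to z > -1/(sigma*power); for power <= 0
    to z < 1/(sigma*|power|).  In both cases the renormaliser is
    T(1/(sigma*|power|)); for power > 0 the mass below -1/(sigma*power) is
    additionally excluded.
    """
    c = 1.0 / (sigma * np.maximum(np.abs(nu), 1e-300))
    upper = stats.t.cdf(c, dof)
    lower = np.where(np.asarray(nu) > 0, stats.t.cdf(-c, dof), 0.0)
    return lower, upper


def _check_bct_y(y):
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("BCT is defined for y > 0 only")
    return y


def bct_cdf(y, params: BctParams):
    """Cumulative probability of the Box-Cox t distribution at ``y`` (> 0)."""
    y = _check_bct_y(y)
    z = _bct_z(y, params.location, params.scale, params.power)
    lower, upper = _bct_trunc(params.scale, params.power, params.dof)
    p = (stats.t.cdf(z, params.dof) - lower) / upper
    return np.clip(p, 0.0, 1.0)


def bct_quantile(p, params: BctParams):
    """Quantile of the Box-Cox t distribution; exact inverse of :func:`bct_cdf`."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p must lie strictly within (0, 1)")
    mu, sigma, nu, dof = params.location, params.scale, params.power, params.dof
    lower, upper = _bct_trunc(sigma, nu, dof)
    z = stats.t.ppf(p * upper + lower, dof)
    if nu == 0.0:
        return mu * np.exp(sigma * z)
    return mu * np.power(np.maximum(1.0 + sigma * nu * z, 1e-15), 1.0 / nu)


def _bct_logpdf_arrays(y, mu, sigma, nu, dof):
    """Vectorised BCT log density (parameters broadcastable against y)."""
    y = np.asarray(y, dtype=float)
    z = _bct_z(y, mu, sigma, nu)
    _, upper = _bct_trunc(sigma, nu, dof)
    nu_arr = np.asarray(nu, dtype=float)
    return (
        (nu_arr - 1.0) * np.log(y)
        - nu_arr * np.log(mu)
        - np.log(sigma)
        + stats.t.logpdf(z, dof)
        - np.log(upper)
    )


def bct_logpdf(y, params: BctParams):
    """Log density of the Box-Cox t distribution at ``y`` (> 0)."""
    y = _check_bct_y(y)
    return _bct_logpdf_arrays(y, params.location, params.scale, params.power, params.dof)
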