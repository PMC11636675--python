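"""Analytic ground-truth conditional distributions g(y|x).

A :class:`GroundTruth` specifies the mean and standard deviation of a scalar
biomarker (the running example is hippocampal volume in mm^3) as smooth
functions of age over a closed age range, with a Gaussian conditional
distribution.  Because the ground truth is analytic, the true percentile
curves ``y_g(x, p)`` (the value with G(y_g|x) = p) and the true cumulative
G(y|x) are available exactly, which is what makes bias measurable in the
simulations.

Two built-in cases are provided:

* ``LinMean_ConstVar`` — mu(x) = 5000 - 7x, sigma(x) = 300: every percentile
  curve is a straight line and all are parallel.
* ``NonLinMean_NonConstVar`` — a sigmoid-blended piecewise-linear mean that
  peaks near age 63 with age-increasing spread:
  mu(x) = -70 (x-65) s((x-65)/10) + 20 (x-65) + 6000,
  sigma(x) = 5 (x-65) s((x-65)/10) + (x-65) + 200,
  with s the logistic sigmoid; mu(65) = 6000 and sigma(65) = 200.

Custom ground truths (including non-Gaussian conditional families) can be
registered with :func:`register_ground_truth`.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "GroundTruth",
    "make_ground_truth",
    "register_ground_truth",
    "gt_quantile",
    "gt_cdf",
    "DEFAULT_AGE_RANGE",
]

DEFAULT_AGE_RANGE: Tuple[float, float] = (45.0, 80.0)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """A conditional distribution p(y|x) with analytic quantile and cdf."""

    mean_fn: Callable[[np.ndarray], np.ndarray]
    sd_fn: Callable[[np.ndarray], np.ndarray]
    family: str = "gaussian"
    age_range: Tuple[float, float] = DEFAULT_AGE_RANGE
    name: str = "custom"

    def check_ages(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self.age_range
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(
                f"age outside the ground-truth range [{lo}, {hi}]; "
                "no extrapolation is supported"
            )
        return x


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _lin_mean(x):
    return 5000.0 - 7.0 * np.asarray(x, dtype=float)


def _lin_sd(x):
    return np.full_like(np.asarray(x, dtype=float), 300.0)


def _nonlin_mean(x):
    x = np.asarray(x, dtype=float)
    d = x - 65.0
    return -70.0 * d * _sigmoid(d / 10.0) + 20.0 * d + 6000.0


def _nonlin_sd(x):
    x = np.asarray(x, dtype=float)
    d = x - 65.0
    return 5.0 * d * _sigmoid(d / 10.0) + d + 200.0


_REGISTRY: Dict[str, GroundTruth] = {}


def register_ground_truth(gt: GroundTruth) -> None:
    """Register a custom ground truth so it can be selected by name."""
    _REGISTRY[gt.name] = gt


register_ground_truth(
    GroundTruth(mean_fn=_lin_mean, sd_fn=_lin_sd, name="LinMean_ConstVar")
)
register_ground_truth(
    GroundTruth(mean_fn=_nonlin_mean, sd_fn=_nonlin_sd, name="NonLinMean_NonConstVar")
)


def make_ground_truth(kind: str) -> GroundTruth:
    """Return a registered ground truth by name.

    Built-in kinds are ``"LinMean_ConstVar"`` and ``"NonLinMean_NonConstVar"``.
    """
    try:
        return _REGISTRY[kind]
    except KeyError:
        raise ValueError(
            f"unknown ground-truth kind {kind!r}; known: {sorted(_REGISTRY)}"
        ) from None


def gt_quantile(gt: GroundTruth, x, p):
    """True percentile curve value y_g(x, p), i.e. G(y_g(x,p)|x) = p."""
    x = gt.check_ages(x)
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("p must lie strictly within (0, 1)")
    if gt.family != "gaussian":
        raise NotImplementedError(f"family {gt.family!r} has no analytic quantile")
    return gt.mean_fn(x) + gt.sd_fn(x) * stats.norm.ppf(p)


def gt_cdf(gt: GroundTruth, x, y):
    """True cumulative probability G(y|x) of the ground truth."""
    x = gt.check_ages(x)
    if gt.family != "gaussian":
        raise NotImplementedError(f"family {gt.family!r} has no analytic cdf")
    return stats.norm.cdf(np.asarray(y, dtype=float), loc=gt.mean_fn(x), scale=gt.sd_fn(x))


def gt_mean_volume(gt: GroundTruth, ages=None) -> float:
    """Mean of mu(x) over a set of ages (default: integer-age grid).

    Used as the denominator when volume-domain errors are expressed as a
    percentage of the mean.
    """
    if ages is None:
        lo, hi = gt.age_range
        ages = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    return float(np.mean(gt.mean_fn(np.asarray(ages, dtype=float))))
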