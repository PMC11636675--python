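"""Model-free sliding-window percentile-curve estimation.

Two window rules are provided, both followed by light Gaussian smoothing of
the raw curves along the age grid:

* fixed-width window (default 5 years, tag ``SliWinW5``): the empirical
  quantile of all values whose ages fall within ±width/2 of the grid age;
* data-fraction window (default 10% of participants, tag ``SliWinP10``):
  the quantile of the k ages nearest the grid age, k = ceil(fraction * Ns),
  so windows widen automatically where data are sparse (the range ends).

Empirical quantiles use linear interpolation of order statistics (the
"type 7" rule).  Smoothing uses a Gaussian kernel with a full width at half
maximum of 5 years by default, with kernel weights renormalised where the
kernel is truncated at the grid edges so a constant curve is preserved.
Percentile curves that cross after smoothing are repaired by sorting values
within each grid age (recorded in ``fit_metadata``).
"""

from __future__ import annotations

import math

import numpy as np

from .curves import DEFAULT_FIT_GRID, PercentileCurveSet
from .sampling import SimulatedSample

__all__ = ["fit_window_fixed", "fit_window_fraction"]

_FWHM_TO_SD = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


def _min_points(percentiles) -> int:
    pmin = min(min(p, 1.0 - p) for p in percentiles)
    return int(max(5, math.ceil(1.0 / pmin) / 4.0))


def _smooth(age_grid, raw, valid, fwhm):
    """Gaussian smoothing along the grid, renormalised over valid points."""
    if fwhm <= 0:
        return raw.copy()
    sd = fwhm / _FWHM_TO_SD
    d = age_grid[None, :] - age_grid[:, None]
    k = np.exp(-0.5 * (d / sd) ** 2)
    k *= valid[None, :]
    norm = k.sum(axis=1)
    out = np.full_like(raw, np.nan)
    ok = norm > 0
    out[:, ok] = (raw[:, valid] @ k[np.ix_(ok, valid)].T) / norm[ok]
    return out


def _finalise(age_grid, percentiles, raw, valid, fwhm, tag, meta):
    smoothed = _smooth(age_grid, np.where(valid[None, :], raw, 0.0), valid, fwhm)
    smoothed[:, ~valid] = np.nan
    sorted_curves = np.sort(smoothed, axis=0)
    crossings = int(np.sum(~np.isclose(sorted_curves, smoothed, equal_nan=True)))
    meta = dict(meta, crossings_repaired=crossings)
    return PercentileCurveSet(
        age_grid=age_grid,
        percentiles=np.asarray(percentiles, dtype=float),
        curves=sorted_curves,
        method_tag=tag,
        valid=valid,
        fit_metadata=meta,
    )


def _check_sample(sample: SimulatedSample) -> None:
    if len(np.unique(sample.ages)) < 2:
        raise ValueError("sliding-window fit needs at least 2 distinct ages")


def fit_window_fixed(
    sample: SimulatedSample,
    width: float = 5.0,
    fwhm: float = 5.0,
    percentiles=(0.01, 0.05, 0.10),
    age_grid=None,
) -> PercentileCurveSet:
    """Fixed-width sliding-window percentile curves (``SliWinW5`` default).

    Grid points whose window holds fewer than max(5, ceil(1/min(p,1-p))/4)
    points are flagged invalid in the returned mask rather than dropped.
    """
    _check_sample(sample)
    age_grid = DEFAULT_FIT_GRID if age_grid is None else np.asarray(age_grid, float)
    percentiles = np.asarray(percentiles, dtype=float)
    need = _min_points(percentiles)
    order = np.argsort(sample.ages, kind="stable")
    ages, values = sample.ages[order], sample.values[order]
    half = width / 2.0
    raw = np.full((len(percentiles), len(age_grid)), np.nan)
    valid = np.zeros(len(age_grid), dtype=bool)
    lo = np.searchsorted(ages, age_grid - half, side="left")
    hi = np.searchsorted(ages, age_grid + half, side="right")
    for j, (i0, i1) in enumerate(zip(lo, hi)):
        if i1 - i0 >= need:
            raw[:, j] = np.quantile(values[i0:i1], percentiles)
            valid[j] = True
    return _finalise(
        age_grid, percentiles, raw, valid, fwhm, "SliWinW%g" % width,
        {"width": width, "fwhm": fwhm, "min_points": need},
    )


def fit_window_fraction(
    sample: SimulatedSample,
    fraction: float = 0.10,
    fwhm: float = 5.0,
    percentiles=(0.01, 0.05, 0.10),
    age_grid=None,
) -> PercentileCurveSet:
    """Data-fraction sliding-window percentile curves (``SliWinP10`` default).

    At each grid age the ceil(fraction * Ns) participants nearest in age are
    selected (age-distance ties broken by smaller participant index).
    """
    _check_sample(sample)
    n = len(sample.ages)
    k = int(math.ceil(fraction * n))
    if k < 10:
        raise ValueError("fraction window needs Ns * fraction >= 10")
    age_grid = DEFAULT_FIT_GRID if age_grid is None else np.asarray(age_grid, float)
    percentiles = np.asarray(percentiles, dtype=float)
    raw = np.empty((len(percentiles), len(age_grid)))
    half_widths = np.empty(len(age_grid))
    idx = np.arange(n)
    for j, c in enumerate(age_grid):
        dist = np.abs(sample.ages - c)
        sel = np.lexsort((idx, dist))[:k]
        raw[:, j] = np.quantile(sample.values[sel], percentiles)
        half_widths[j] = dist[sel].max()
    valid = np.ones(len(age_grid), dtype=bool)
    return _finalise(
        age_grid, percentiles, raw, valid, fwhm, "SliWinP%g" % (100 * fraction),
        {"fraction": fraction, "fwhm": fwhm, "window_half_widths": half_widths},
    )
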