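"""Error measures of estimated percentile curves against an analytic truth.

Two complementary errors are computed for each (age, percentile) pair:

* ``E1 = y_f(x, p) - y_g(x, p)`` — the volume-domain difference between the
  estimated and true percentile curves (same units as the biomarker);
* ``E2 = G(y_f(x, p) | x) - p`` — the probability-domain error: the true
  population fraction lying below the estimated curve minus the nominal
  percentile.  A fitted curve sitting above the truth gives E2 > 0.

Because the percentile spacing of a distribution widens in the tails, a
small E2 maps to a large E1 at outer percentiles (locally
``E1/E2 ~ sigma(x) / phi(Phi^-1(p))`` for a Gaussian truth).

Across replicates the summaries are: 95% range (97.5th - 2.5th percentile)
of E1 for pure variance, mean |E2| (MAE) for combined bias+variance, median
E1 for bias and interquartile range of E1 for variance.  Age-averaged
values weight every age on the evaluation grid equally, regardless of how
many participants have that age, so edge behaviour is not washed out.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Sequence

import numpy as np
import pandas as pd

from .curves import PercentileCurveSet
from .ground_truth import GroundTruth, gt_cdf, gt_quantile

__all__ = [
    "ErrorSurface",
    "compute_errors",
    "stack_errors",
    "summarize",
    "binomial_min_n",
]


@dataclasses.dataclass
class ErrorSurface:
    """E1/E2 values per (replicate, percentile, age), plus labels.

    e1 and e2 have shape (n_replicates, n_percentiles, n_ages); invalid
    grid points are NaN and are excluded from summaries (counted in
    ``n_missing``).
    """

    age_grid: np.ndarray
    percentiles: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    gt_tag: str = ""
    method_tag: str = ""
    ns: int = 0

    @property
    def n_replicates(self) -> int:
        return self.e1.shape[0]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.e1).sum())


def compute_errors(curves: PercentileCurveSet, gt: GroundTruth) -> ErrorSurface:
    """E1 and E2 of one fitted curve set against the analytic ground truth."""
    x = curves.age_grid
    gt.check_ages(x)
    P = curves.percentiles
    y_true = np.stack([gt_quantile(gt, x, p) for p in P])
    e1 = curves.curves - y_true
    e2 = np.stack([gt_cdf(gt, x, curves.curves[i]) for i in range(len(P))]) - P[:, None]
    invalid = ~curves.valid
    e1[:, invalid] = np.nan
    e2[:, invalid] = np.nan
    return ErrorSurface(
        age_grid=x,
        percentiles=P,
        e1=e1[None, :, :],
        e2=e2[None, :, :],
        gt_tag=gt.name,
        method_tag=curves.method_tag,
    )


def stack_errors(surfaces: Sequence[ErrorSurface]) -> ErrorSurface:
    """Stack per-replicate error surfaces into one multi-replicate surface."""
    first = surfaces[0]
    return ErrorSurface(
        age_grid=first.age_grid,
        percentiles=first.percentiles,
        e1=np.concatenate([s.e1 for s in surfaces], axis=0),
        e2=np.concatenate([s.e2 for s in surfaces], axis=0),
        gt_tag=first.gt_tag,
        method_tag=first.method_tag,
        ns=first.ns,
    )


def _nanq(a, q, axis):
    with np.errstate(all="ignore"):
        return np.nanquantile(a, q, axis=axis, method="linear")


def summarize(errors: ErrorSurface, mean_volume: float) -> pd.DataFrame:
    """Cross-replicate summaries of an error surface, tidy per-age + averaged.

    Metrics per (percentile, age): range95_e1 (and as % of ``mean_volume``),
    mae_e2, median_e1 (bias), iqr_e1 (variance) — plus rows with
    age == "mean" holding the equal-weight average over the grid ages.
    Requires at least 2 replicates for the spread metrics.
    """
    e1, e2 = errors.e1, errors.e2
    nd = errors.n_replicates
    enough = nd >= 2
    import warnings

    with warnings.catch_warnings():
        # all-NaN ages (flagged-invalid grid points) legitimately yield NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        per_age = {
            "range95_e1": _nanq(e1, 0.975, 0) - _nanq(e1, 0.025, 0) if enough else np.full(e1.shape[1:], np.nan),
            "mae_e2": np.nanmean(np.abs(e2), axis=0),
            "median_e1": _nanq(e1, 0.5, 0),
            "iqr_e1": _nanq(e1, 0.75, 0) - _nanq(e1, 0.25, 0) if enough else np.full(e1.shape[1:], np.nan),
        }
        mean_over_ages = {m: np.nanmean(v, axis=1) for m, v in per_age.items()}
    rows: List[dict] = []
    base = dict(gt=errors.gt_tag, method=errors.method_tag, ns=errors.ns)
    for metric, grid in per_age.items():
        for i, p in enumerate(errors.percentiles):
            vals = grid[i]
            for j, age in enumerate(errors.age_grid):
                rows.append(dict(base, percentile=p, metric=metric,
                                 scope="per-age", age=age, value=vals[j]))
            rows.append(dict(base, percentile=p, metric=metric,
                             scope="mean-over-ages", age=np.nan,
                             value=float(mean_over_ages[metric][i])))
    df = pd.DataFrame(rows)
    # E1 metrics also as percent of the mean volume
    pct = df[df.metric.isin(["range95_e1", "median_e1", "iqr_e1"])].copy()
    pct["metric"] = pct["metric"] + "_pct"
    pct["value"] = 100.0 * pct["value"] / mean_volume
    out = pd.concat([df, pct], ignore_index=True)
    out.attrs["n_missing"] = errors.n_missing
    out.attrs["n_replicates"] = nd
    return out


def binomial_min_n(p: float, half_width: float) -> int:
    """Smallest N with binomial sd sqrt(p(1-p)/N) <= half_width.

    This is the model-free lower bound on the single-bin sample size needed
    to estimate a percentile p to +/- half_width; e.g. p = 0.01 needs 396
    participants for +/-0.005 and 2475 for +/-0.002.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly within (0, 1)")
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    ratio = p * (1.0 - p) / (half_width * half_width)
    n = max(1, math.ceil(ratio * (1.0 - 1e-12)))
    while p * (1.0 - p) / n > half_width * half_width * (1.0 + 1e-12):
        n += 1
    return n
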