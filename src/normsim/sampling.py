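"""Age designs and replicate value simulation.

The simulation protocol fixes a single vector of participant ages per sample
size (the *age design*) and redraws only the biomarker values across
replicates, so that replicate-to-replicate variation isolates sampling noise
in the values.  Ages are drawn from a piecewise-linear density over the age
range; the default density thins toward both ends of the range, emulating
the age distribution of a large imaging cohort where recruitment falls off
at the extremes.

Randomness is counter-based: every stream is derived from
``SeedSequence([base_seed, n, replicate_index])`` so any replicate can be
regenerated independently of execution order or process restarts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .ground_truth import GroundTruth

__all__ = [
    "AgeDesign",
    "SimulatedSample",
    "DEFAULT_AGE_DENSITY",
    "sample_ages",
    "simulate_sample",
    "write_sample",
    "read_sample",
]

# Relative density heights at age breakpoints; linear in between, normalised
# internally.  Chosen to put most mass in the late 50s to 70 and little at
# the range ends ("end-thinned").
DEFAULT_AGE_DENSITY: Tuple[Tuple[float, float], ...] = (
    (45.0, 0.2),
    (55.0, 0.8),
    (62.0, 1.0),
    (70.0, 0.9),
    (80.0, 0.1),
)


@dataclasses.dataclass(frozen=True)
class AgeDesign:
    """A fixed vector of participant ages shared by all replicates of one Ns."""

    ages: np.ndarray
    design_seed: int
    density_spec: Tuple[Tuple[float, float], ...] = DEFAULT_AGE_DENSITY

    @property
    def n(self) -> int:
        return len(self.ages)


@dataclasses.dataclass(frozen=True)
class SimulatedSample:
    """One replicate: the shared ages paired with freshly drawn values."""

    ages: np.ndarray
    values: np.ndarray
    replicate_index: int = 0
    value_seed: int = 0


def _normalise_density(density_spec) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Breakpoints, heights, and per-segment cumulative mass (normalised)."""
    spec = np.asarray(sorted(density_spec), dtype=float)
    if spec.ndim != 2 or spec.shape[0] < 2 or spec.shape[1] != 2:
        raise ValueError("density_spec must list >= 2 (age, height) pairs")
    x, h = spec[:, 0], spec[:, 1]
    if np.any(h < 0):
        raise ValueError("density heights must be non-negative")
    seg_mass = 0.5 * (h[:-1] + h[1:]) * np.diff(x)
    total = seg_mass.sum()
    if total <= 0:
        raise ValueError("density_spec has non-positive total mass")
    cum = np.concatenate([[0.0], np.cumsum(seg_mass)]) / total
    return x, h / total, cum


def sample_ages(
    n: int,
    density_spec=DEFAULT_AGE_DENSITY,
    seed: int = 0,
) -> AgeDesign:
    """Draw ``n`` i.i.d. ages by exact inverse-cdf sampling.

    The cdf of a piecewise-linear density is piecewise quadratic; each
    uniform draw is mapped through the analytic inverse of its segment.
    Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need at least 2 participants")
    x, h, cum = _normalise_density(density_spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(n)]))
    u = rng.random(n)
    seg = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, len(x) - 2)
    x0, x1 = x[seg], x[seg + 1]
    h0, h1 = h[seg], h[seg + 1]
    k = (h1 - h0) / (x1 - x0)
    t = u - cum[seg]  # mass to absorb within the segment
    # solve h0*w + k*w^2/2 = t for w = age - x0 (stable quadratic root)
    disc = np.sqrt(np.maximum(h0 * h0 + 2.0 * k * t, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(np.abs(k) > 1e-14, (disc - h0) / k, t / np.maximum(h0, 1e-300))
    ages = np.clip(x0 + w, x[0], x[-1])
    return AgeDesign(ages=ages, design_seed=int(seed), density_spec=tuple(map(tuple, np.asarray(density_spec))))


def simulate_sample(
    gt: GroundTruth,
    design: AgeDesign,
    replicate_index: int = 0,
    base_seed: int = 0,
) -> SimulatedSample:
    """Draw one replicate: values[i] ~ g(.|ages[i]) on the fixed age design.

    The replicate's stream is seeded by (base_seed, n, replicate_index), so
    replicates are independent and may be generated in any order.
    """
    ages = design.ages
    gt.check_ages(ages)
    if gt.family != "gaussian":
        raise NotImplementedError(f"sampling not implemented for family {gt.family!r}")
    ss = np.random.SeedSequence([int(base_seed), int(design.n), int(replicate_index)])
    rng = np.random.default_rng(ss)
    z = rng.standard_normal(design.n)
    values = gt.mean_fn(ages) + gt.sd_fn(ages) * z
    return SimulatedSample(
        ages=ages,
        values=values,
        replicate_index=int(replicate_index),
        value_seed=int(base_seed),
    )


def write_sample(sample: SimulatedSample, path, gt_name: str | None = None) -> None:
    """Write a sample as two-column delimited text with a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"age": sample.ages, "value": sample.values}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
    meta = {
        "n": int(len(sample.ages)),
        "replicate_index": sample.replicate_index,
        "value_seed": sample.value_seed,
        "ground_truth": gt_name,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_sample(path) -> SimulatedSample:
    """Read a two-column (age, value) delimited-text sample."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = [c.lower() for c in df.columns]
    if "age" in cols and "value" in cols:
        ages = df[df.columns[cols.index("age")]].to_numpy(float)
        values = df[df.columns[cols.index("value")]].to_numpy(float)
    else:
        ages = df.iloc[:, 0].to_numpy(float)
        values = df.iloc[:, 1].to_numpy(float)
    meta_path = Path(path).with_suffix(Path(path).suffix + ".json")
    rep, seed = 0, 0
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        rep = int(meta.get("replicate_index", 0))
        seed = int(meta.get("value_seed", 0))
    return SimulatedSample(ages=ages, values=values, replicate_index=rep, value_seed=seed)
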