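"""Container for estimated percentile curves on an evaluation age grid."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

__all__ = ["PercentileCurveSet", "DEFAULT_FIT_GRID", "DEFAULT_EVAL_GRID"]

# Fine grid used for fitting/smoothing; coarse integer-age grid for evaluation.
DEFAULT_FIT_GRID = np.arange(45.0, 80.0 + 1e-9, 0.25)
DEFAULT_EVAL_GRID = np.arange(45.0, 81.0)


@dataclasses.dataclass
class PercentileCurveSet:
    """Estimated percentile-curve values y_f(x, p) for one fitted model.

    curves has shape (len(percentiles), len(age_grid)); ``valid`` flags grid
    points with enough data to trust (invalid points are kept, not dropped,
    so downstream code can count them).
    """

    age_grid: np.ndarray
    percentiles: np.ndarray
    curves: np.ndarray
    method_tag: str = ""
    valid: np.ndarray | None = None
    fit_metadata: Dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.percentiles = np.asarray(self.percentiles, dtype=float)
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.shape != (len(self.percentiles), len(self.age_grid)):
            raise ValueError("curves must have shape (n_percentiles, n_ages)")
        if self.valid is None:
            self.valid = np.ones(len(self.age_grid), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def at_ages(self, ages) -> "PercentileCurveSet":
        """Restrict to a subset of grid ages (e.g. the coarse evaluation grid)."""
        ages = np.asarray(ages, dtype=float)
        idx = np.searchsorted(self.age_grid, ages)
        idx = np.clip(idx, 0, len(self.age_grid) - 1)
        if not np.allclose(self.age_grid[idx], ages, atol=1e-8):
            raise ValueError("requested ages are not on the curve grid")
        return PercentileCurveSet(
            age_grid=ages,
            percentiles=self.percentiles,
            curves=self.curves[:, idx],
            method_tag=self.method_tag,
            valid=self.valid[idx],
            fit_metadata=dict(self.fit_metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.curves.T,
            columns=[f"p{100 * p:g}" for p in self.percentiles],
        )
        df.insert(0, "age", self.age_grid)
        df["valid"] = self.valid.astype(int)
        return df

    def write(self, path) -> None:
        self.to_frame().to_csv(Path(path), sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read(cls, path, method_tag: str = "") -> "PercentileCurveSet":
        df = pd.read_csv(path, sep="\t")
        pcols = [c for c in df.columns if c.startswith("p") and c != "valid"]
        percentiles = np.array([float(c[1:]) / 100.0 for c in pcols])
        valid = df["valid"].to_numpy(bool) if "valid" in df else None
        return cls(
            age_grid=df["age"].to_numpy(float),
            percentiles=percentiles,
            curves=df[pcols].to_numpy(float).T,
            method_tag=method_tag,
            valid=valid,
        )
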