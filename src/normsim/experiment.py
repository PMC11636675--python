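"""Factorial simulation experiments: ground truth x method x sample size.

This is the power-calculation workflow: pick ground truths, fitting
methods, sample sizes and percentiles; for each cell regenerate the fixed
age design, simulate ``nd`` replicate samples, fit every method, compare
the fitted percentile curves with the analytic truth on the evaluation
grid, and aggregate the E1/E2 error summaries into one tidy table.  A JSON
run manifest records the configuration, per-cell completion and any
failures so a run can be reproduced or audited.

Replicates are seeded independently of execution order, so cells and
replicates may be computed in any order (and in parallel).  Partial
failures (e.g. a non-converged fit) never abort a run; they are counted,
excluded from summaries, and a cell with more than 20% failed replicates
is flagged in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from concurrent.futures import ProcessPoolExecutor
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import DEFAULT_EVAL_GRID, DEFAULT_FIT_GRID, PercentileCurveSet
from .distreg import DistRegSpec, fit_distreg, predict_percentiles
from .evaluation import ErrorSurface, binomial_min_n, compute_errors, stack_errors, summarize
from .ground_truth import gt_mean_volume, make_ground_truth
from .sampling import DEFAULT_AGE_DENSITY, sample_ages, simulate_sample
from .sliding_window import fit_window_fixed, fit_window_fraction

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "run_experiment",
    "power_report",
    "desk_scale_config",
    "paper_scale_config",
    "load_config",
]

DESK_METHODS = ("SliWinW5", "SliWinP10", "SHASH-linear", "SHASH-mu-sigma")
PAPER_METHODS = DESK_METHODS + ("SHASH-mu", "BCT-linear", "BCT-mu", "BCT-mu-sigma")


@dataclasses.dataclass
class ExperimentConfig:
    gt_kinds: Tuple[str, ...] = ("LinMean_ConstVar", "NonLinMean_NonConstVar")
    methods: Tuple[str, ...] = DESK_METHODS
    ns_list: Tuple[int, ...] = (100, 500, 2000)
    nd: int = 50
    percentiles: Tuple[float, ...] = (0.01, 0.05, 0.10)
    base_seed: int = 0
    density_spec: Tuple[Tuple[float, float], ...] = DEFAULT_AGE_DENSITY
    eval_grid: Tuple[float, ...] = tuple(DEFAULT_EVAL_GRID)
    outdir: Optional[str] = None
    n_jobs: int = 1

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["density_spec"] = [list(p) for p in self.density_spec]
        return d


def desk_scale_config(**overrides) -> ExperimentConfig:
    """Desk-scale profile: three sample sizes, 50 replicates, four methods."""
    return ExperimentConfig(**overrides)


def paper_scale_config(**overrides) -> ExperimentConfig:
    """Full-scale profile: all sample sizes up to 50,000 and all methods.

    Replicate counts default to 100 here (the headline study used 1000);
    expect a long run.
    """
    defaults = dict(
        methods=PAPER_METHODS,
        ns_list=(50, 100, 200, 500, 1000, 2000, 5000, 50000),
        nd=100,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


def load_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "density_spec" in raw:
        raw["density_spec"] = tuple(tuple(p) for p in raw["density_spec"])
    for key in ("gt_kinds", "methods", "ns_list", "percentiles", "eval_grid"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ExperimentConfig(**raw)


# ---------------------------------------------------------------------------
# Method resolution
# ---------------------------------------------------------------------------

def _resolve_method(tag: str):
    """Map a method tag to a (sample -> PercentileCurveSet) fitter factory."""
    if tag == "SliWinW5":
        return dict(kind="window_fixed", width=5.0, fwhm=5.0)
    if tag == "SliWinP10":
        return dict(kind="window_fraction", fraction=0.10, fwhm=5.0)
    for family in ("SHASH", "BCT"):
        if tag.startswith(family + "-"):
            suffix = tag[len(family) + 1:]
            structure = {"linear": "linear", "mu": "mu_spline",
                         "mu-sigma": "mu_sigma_spline"}.get(suffix)
            if structure is not None:
                return dict(kind="distreg", family=family, structure=structure)
    raise ValueError(f"unknown method tag {tag!r}")


def _fit_one(task) -> Tuple[str, int, Optional[ErrorSurface], Optional[str]]:
    """Fit one (replicate, method) and return its error surface (worker-safe)."""
    (gt_name, ns, rep, method_tag, percentiles, eval_grid, base_seed,
     density_spec, design_seed) = task
    gt = make_ground_truth(gt_name)
    design = sample_ages(ns, density_spec, seed=design_seed)
    sample = simulate_sample(gt, design, replicate_index=rep, base_seed=base_seed)
    m = _resolve_method(method_tag)
    try:
        if m["kind"] == "window_fixed":
            curves = fit_window_fixed(sample, width=m["width"], fwhm=m["fwhm"],
                                      percentiles=percentiles,
                                      age_grid=DEFAULT_FIT_GRID).at_ages(eval_grid)
        elif m["kind"] == "window_fraction":
            curves = fit_window_fraction(sample, fraction=m["fraction"], fwhm=m["fwhm"],
                                         percentiles=percentiles,
                                         age_grid=DEFAULT_FIT_GRID).at_ages(eval_grid)
        else:
            if m["family"] == "BCT" and np.any(sample.values <= 0):
                return method_tag, rep, None, "rejected: non-positive values for BCT"
            spec = DistRegSpec(family=m["family"], structure=m["structure"])
            fit = fit_distreg(sample, spec, age_range=gt.age_range,
                              seed=base_seed + rep)
            if not fit.converged:
                return method_tag, rep, None, "fit did not converge"
            curves = predict_percentiles(fit, np.asarray(eval_grid), percentiles)
        curves.method_tag = method_tag
        surf = compute_errors(curves, gt)
        surf.ns = ns
        return method_tag, rep, surf, None
    except Exception as exc:  # recorded, never fatal to the run
        return method_tag, rep, None, f"{type(exc).__name__}: {exc}"


@dataclasses.dataclass
class RunManifest:
    config: Dict
    version: str
    cells: List[Dict]
    failures: List[Dict]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


def run_experiment(config: ExperimentConfig) -> Tuple[pd.DataFrame, RunManifest]:
    """Run the full factorial grid and return (summary table, manifest).

    The summary table is tidy: one row per (gt, method, ns, percentile,
    metric, scope, age).  If ``config.outdir`` is set, the table and the
    manifest are also written there as ``summary.tsv`` / ``manifest.json``.
    """
    cells: List[Dict] = []
    failures: List[Dict] = []
    summaries: List[pd.DataFrame] = []
    eval_grid = np.asarray(config.eval_grid, dtype=float)

    for gt_name in config.gt_kinds:
        gt = make_ground_truth(gt_name)
        mean_vol = gt_mean_volume(gt)
        for ns in config.ns_list:
            tasks = [
                (gt_name, ns, rep, tag, tuple(config.percentiles),
                 tuple(eval_grid), config.base_seed, config.density_spec,
                 config.base_seed)
                for rep in range(config.nd)
                for tag in config.methods
            ]
            if config.n_jobs > 1:
                with ProcessPoolExecutor(max_workers=config.n_jobs) as ex:
                    results = list(ex.map(_fit_one, tasks, chunksize=4))
            else:
                results = [_fit_one(t) for t in tasks]
            by_method: Dict[str, List[ErrorSurface]] = {m: [] for m in config.methods}
            for tag, rep, surf, err in results:
                if surf is None:
                    failures.append(dict(gt=gt_name, ns=ns, method=tag,
                                         replicate=rep, reason=err))
                else:
                    by_method[tag].append(surf)
            for tag in config.methods:
                done = by_method[tag]
                n_failed = config.nd - len(done)
                cells.append(dict(gt=gt_name, ns=ns, method=tag,
                                  nd_completed=len(done), n_failed=n_failed,
                                  flagged=bool(n_failed > 0.2 * config.nd)))
                if len(done) >= 2:
                    summaries.append(summarize(stack_errors(done), mean_vol))

    summary = (pd.concat(summaries, ignore_index=True)
               if summaries else pd.DataFrame())
    manifest = RunManifest(config=config.to_dict(), version=__version__,
                           cells=cells, failures=failures)
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                       float_format="%.10g")
        manifest.write(out / "manifest.json")
    return summary, manifest


# ---------------------------------------------------------------------------
# Power reports
# ---------------------------------------------------------------------------

def power_report(
    summary: pd.DataFrame,
    question: str,
    metric: str = "mae_e2",
    percentile: float = 0.05,
    method: Optional[str] = None,
    gt: Optional[str] = None,
    age_band: Optional[Tuple[float, float]] = None,
    threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Answer power-calculation questions from an experiment summary.

    ``question="accuracy-at-n"`` tabulates the chosen metric against Ns
    (age-averaged, plus averaged over ``age_band`` if given).
    ``question="n-for-accuracy"`` returns the smallest simulated Ns whose
    age-averaged metric meets ``threshold`` (no interpolation between the
    simulated sizes); the result may be "not achieved".  For
    probability-domain metrics the binomial single-bin bound
    :func:`binomial_min_n` is attached as model-free context.
    """
    df = summary[(summary.metric == metric)
                 & np.isclose(summary.percentile, percentile)]
    if method is not None:
        df = df[df.method == method]
    if gt is not None:
        df = df[df.gt == gt]
    if df.empty:
        raise ValueError("no summary rows match the requested subset")

    if age_band is not None:
        lo, hi = age_band
        ages = df[df.scope == "per-age"]["age"].astype(float)
        if lo < ages.min() or hi > ages.max():
            raise ValueError("requested age band lies outside the evaluated grid")

    grouped = (df[df.scope == "mean-over-ages"]
               .groupby(["gt", "method", "ns"], as_index=False)["value"].mean())
    grouped = grouped.rename(columns={"value": metric})
    if age_band is not None:
        lo, hi = age_band
        per_age = df[(df.scope == "per-age")]
        in_band = per_age[(per_age.age.astype(float) >= lo)
                          & (per_age.age.astype(float) <= hi)]
        band = (in_band.groupby(["gt", "method", "ns"], as_index=False)["value"]
                .mean().rename(columns={"value": f"{metric}_ages_{lo:g}_{hi:g}"}))
        grouped = grouped.merge(band, on=["gt", "method", "ns"])

    if question == "accuracy-at-n":
        return grouped.sort_values(["gt", "method", "ns"]).reset_index(drop=True)

    if question == "n-for-accuracy":
        if threshold is None:
            raise ValueError("n-for-accuracy needs a threshold")
        rows = []
        for (g, m), sub in grouped.groupby(["gt", "method"]):
            sub = sub.sort_values("ns")
            ok = sub[sub[metric] <= threshold]
            rows.append(dict(
                gt=g, method=m, metric=metric, percentile=percentile,
                threshold=threshold,
                min_ns=int(ok.ns.iloc[0]) if len(ok) else None,
                achieved=bool(len(ok)),
            ))
        report = pd.DataFrame(rows)
        if metric.endswith("e2") and threshold > 0:
            report["binomial_lower_bound_n"] = binomial_min_n(percentile, threshold)
        return report

    raise ValueError("question must be 'accuracy-at-n' or 'n-for-accuracy'")
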