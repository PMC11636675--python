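"""Reporting plots generated from experiment summary tables.

Purely a convenience layer: every figure is drawn from the tidy summary
table, never from internal state.  Requires matplotlib (optional extra).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def error_vs_ns(summary: pd.DataFrame, metric: str = "range95_e1_pct",
                percentile: float = 0.05, gt: str | None = None, ax=None):
    """Line plot of an age-averaged error metric against sample size."""
    import matplotlib.pyplot as plt

    df = summary[(summary.metric == metric)
                 & np.isclose(summary.percentile, percentile)
                 & (summary.scope == "mean-over-ages")]
    if gt is not None:
        df = df[df.gt == gt]
    if ax is None:
        _, ax = plt.subplots()
    for method, sub in df.groupby("method"):
        sub = sub.sort_values("ns")
        ax.plot(sub.ns, sub.value, marker="o", label=method)
    ax.set_xscale("log")
    ax.set_xlabel("sample size Ns")
    ax.set_ylabel(metric)
    ax.set_title(f"p = {percentile:g}" + (f", {gt}" if gt else ""))
    ax.legend()
    return ax


def bias_iqr_by_age(summary: pd.DataFrame, method: str, ns: int,
                    gt: str | None = None, axes=None):
    """Per-age median (bias) and IQR (variance) of E1 for one method/Ns."""
    import matplotlib.pyplot as plt

    df = summary[(summary.method == method) & (summary.ns == ns)
                 & (summary.scope == "per-age")]
    if gt is not None:
        df = df[df.gt == gt]
    if axes is None:
        _, axes = plt.subplots(2, 1, sharex=True)
    for metric, ax, label in zip(("median_e1", "iqr_e1"), axes,
                                 ("median E1 (bias)", "IQR E1 (variance)")):
        for p, sub in df[df.metric == metric].groupby("percentile"):
            sub = sub.sort_values("age")
            ax.plot(sub.age.astype(float), sub.value, label=f"p={p:g}")
        ax.set_ylabel(label)
        ax.legend()
    axes[-1].set_xlabel("age (years)")
    return axes
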