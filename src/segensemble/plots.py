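"""Optional figure-style summaries.  Plots are artifacts only — never an
input to any computation."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .metrics import METRIC_NAMES
from .robustness import OutlierBoundary

__all__ = ["plot_threshold_sweep", "plot_per_image_scatter", "plot_size_curve"]


def plot_threshold_sweep(table: pd.DataFrame, path: str | Path) -> None:
    """Mean metric vs probability threshold, one panel per metric."""
    fig, axes = plt.subplots(1, 4, figsize=(14, 3))
    for ax, name in zip(axes, METRIC_NAMES):
        ax.plot(table["p_thr"], table[name], "k.-")
        ax.set_xlabel("$p_{thr}$")
        ax.set_ylabel(name.upper())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_per_image_scatter(model_records: pd.DataFrame,
                           ensemble_records: pd.DataFrame,
                           boundaries: Sequence[OutlierBoundary],
                           metric: str, path: str | Path) -> None:
    """Per-image scatter: dots = single models, stars = ensemble, dashed
    line = the outlier boundary; outliers drawn as asterisk markers."""
    col = {"dsc": "dsc", "rvd": "rvd", "assd": "assd_mm", "mssd": "mssd_mm"}[metric]
    b = next(x for x in boundaries if x.metric == metric and x.source_id is None)
    fig, ax = plt.subplots(figsize=(10, 3.2))
    order = {iid: i for i, iid in
             enumerate(sorted(model_records["image_id"].unique()))}
    for df, marker, size in ((model_records, ".", 18), (ensemble_records, "*", 70)):
        x = df["image_id"].map(order)
        vals = df[col]
        out = vals.apply(b.is_outlier)
        ax.scatter(x[~out], vals[~out], marker=marker, s=size, alpha=0.6)
        ax.scatter(x[out], vals[out], marker="x", s=size, color="crimson")
    ax.axhline(b.cutoff, ls="--", color="gray")
    ax.set_xlabel("image")
    ax.set_ylabel(metric.upper())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_size_curve(summary: pd.DataFrame, path: str | Path,
                    metric: str = "dsc") -> None:
    """Mean ± sd of a metric vs ensemble size from a subsampling summary."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(summary["size"], summary[f"{metric}_mean"],
                yerr=summary[f"{metric}_sd"].fillna(0.0), fmt="o-")
    ax.set_xlabel("ensemble size")
    ax.set_ylabel(f"mean {metric.upper()}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
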