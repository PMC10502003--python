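"""Robustness analytics for segmentation ensembles.

Single models occasionally fail catastrophically on individual images —
spurious distant components or gross dropouts — even when their average
performance is fine.  This module quantifies how well a fused ensemble
suppresses such failures:

* percentile **outlier boundaries** per organ and metric (DSC below its
  5th percentile; RVD/ASSD/MSSD above their 95th percentiles, over the
  pooled single-model values);
* **high-risk images**: images on which at least one ensemble member
  produced an outlier metric;
* **rescue rates**: the fraction of high-risk images on which the fused
  segmentation is *not* an outlier (the ensemble is judged against the
  single-model boundaries, not its own distribution);
* **ensemble gain** g = L_ens − L_ref per loss metric (Dice loss 1−DSC,
  RVD, ASSD, MSSD), with the mean or the worst single model as reference
  (negative g = improvement), and straight-line **York fits** of the gain
  against the reference loss with errors in both coordinates;
* **ensemble-size subsampling**: metrics of ensembles rebuilt from random
  model subsets drawn without replacement, reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fusion import fuse_average
from .metrics import METRIC_NAMES, evaluate
from .volumes import BinaryMask

__all__ = [
    "OutlierBoundary",
    "LineFit",
    "RescueReport",
    "LOSS_COLUMNS",
    "outlier_boundaries",
    "flag_outliers",
    "high_risk_images",
    "rescue_rates",
    "ensemble_gain",
    "york_fit",
    "subsample_ensembles",
]

#: Metric value column per metric short name in a metric table.
_VALUE_COLUMN = {"dsc": "dsc", "rvd": "rvd", "assd": "assd_mm", "mssd": "mssd_mm"}

#: Loss column names emitted by :func:`ensemble_gain`.
LOSS_COLUMNS = ("dice_loss", "rvd", "assd", "mssd")


@dataclass(frozen=True)
class OutlierBoundary:
    """Percentile cutoff separating ordinary from outlier values of one
    metric for one organ.  ``direction`` is "below" for DSC (low Dice is
    bad) and "above" for the loss-like metrics."""

    organ: str
    metric: str
    percentile: float
    cutoff: float
    direction: str  # "below" | "above"
    source_id: str | None = None  # set in per-model pooling mode

    def is_outlier(self, value: float) -> bool:
        """Strictly beyond the cutoff; values exactly at the boundary (and
        NaN) are not outliers."""
        if math.isnan(value):
            return False
        return value < self.cutoff if self.direction == "below" else value > self.cutoff


def outlier_boundaries(records: pd.DataFrame, percentile: float = 0.05,
                       pooling: str = "pooled") -> list[OutlierBoundary]:
    """Percentile outlier boundaries from single-model metric records.

    ``records`` is a metric table (one row per image x model).  For each
    organ and metric the cutoff is the linear-interpolation quantile of
    the pooled values: the ``percentile`` quantile for DSC, the
    ``1 − percentile`` quantile otherwise.  ``pooling="per_model"``
    computes boundaries per (organ, model) instead.
    """
    if records.empty:
        raise ValueError("empty record set")
    if not 0.0 < percentile <= 0.5:
        raise ValueError(f"percentile must lie in (0, 0.5], got {percentile}")
    if pooling not in ("pooled", "per_model"):
        raise ValueError(f"pooling must be 'pooled' or 'per_model', got {pooling!r}")

    group_cols = ["organ"] if pooling == "pooled" else ["organ", "source_id"]
    out: list[OutlierBoundary] = []
    for key, grp in records.groupby(group_cols, sort=True):
        organ = key[0] if isinstance(key, tuple) else key
        source = key[1] if pooling == "per_model" else None
        for metric in METRIC_NAMES:
            vals = grp[_VALUE_COLUMN[metric]].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            if metric == "dsc":
                cutoff, direction = np.quantile(vals, percentile), "below"
            else:
                cutoff, direction = np.quantile(vals, 1.0 - percentile), "above"
            out.append(OutlierBoundary(str(organ), metric, percentile,
                                       float(cutoff), direction, source))
    return out


def _boundary_lookup(boundaries: Sequence[OutlierBoundary]
                     ) -> dict[tuple[str, str, str | None], OutlierBoundary]:
    return {(b.organ, b.metric, b.source_id): b for b in boundaries}


def flag_outliers(records: pd.DataFrame,
                  boundaries: Sequence[OutlierBoundary]) -> pd.DataFrame:
    """Add per-metric boolean ``outlier_<metric>`` columns and ``outlier_any``.

    Every record — single model or fused ensemble — is flagged against the
    boundaries passed in (derived from single models), so a fused result is
    judged on the single-model scale.  With per-model boundaries, records
    whose source has no boundary of its own (e.g. the ensemble) fall back
    to a pooled boundary if present, else an error is raised.
    """
    lookup = _boundary_lookup(boundaries)
    flagged = records.copy()
    any_col = np.zeros(len(records), dtype=bool)
    for metric in METRIC_NAMES:
        col = np.zeros(len(records), dtype=bool)
        values = records[_VALUE_COLUMN[metric]].to_numpy(dtype=float)
        for i, (organ, source) in enumerate(zip(records["organ"], records["source_id"])):
            b = lookup.get((organ, metric, source)) or lookup.get((organ, metric, None))
            if b is None:
                raise KeyError(f"no outlier boundary for organ={organ!r}, metric={metric!r}")
            col[i] = b.is_outlier(values[i])
        flagged[f"outlier_{metric}"] = col
        any_col |= col
    flagged["outlier_any"] = any_col
    return flagged


def high_risk_images(flagged_model_records: pd.DataFrame) -> dict[str, set[str]]:
    """Images on which at least one model produced an outlier metric,
    per organ.  Pass *single-model* records only: by definition an
    ensemble-only outlier does not make an image high-risk."""
    out: dict[str, set[str]] = {}
    df = flagged_model_records
    risky = df[df["outlier_any"]]
    for organ, grp in risky.groupby("organ"):
        out[str(organ)] = set(grp["image_id"].astype(str))
    return out


@dataclass(frozen=True)
class RescueReport:
    """Per-metric fraction of high-risk images on which the fused
    segmentation stayed inside the outlier boundary.  ``rates`` values are
    None when the high-risk set is empty (undefined, deliberately neither
    0 nor 1)."""

    rates: Mapping[str, float | None]
    n_high_risk: int
    n_images: int

    @property
    def high_risk_fraction(self) -> float:
        return self.n_high_risk / self.n_images if self.n_images else math.nan


def rescue_rates(high_risk: Mapping[str, set[str]] | set[str],
                 flagged_ensemble_records: pd.DataFrame) -> RescueReport:
    """How often the ensemble avoids the outlier region on high-risk images.

    ``high_risk`` is the output of :func:`high_risk_images` (or a plain set
    of image ids for a single-organ study); ``flagged_ensemble_records``
    are the fused-segmentation records flagged against the *single-model*
    boundaries.
    """
    df = flagged_ensemble_records
    if isinstance(high_risk, Mapping):
        pairs = {(o, i) for o, ids in high_risk.items() for i in ids}
        mask = [(str(o), str(i)) in pairs
                for o, i in zip(df["organ"], df["image_id"])]
    else:
        ids = {str(i) for i in high_risk}
        mask = [str(i) in ids for i in df["image_id"]]
    sub = df[np.asarray(mask, dtype=bool)]
    n_hr = len(sub)
    n_images = df[["organ", "image_id"]].drop_duplicates().shape[0]
    if n_hr == 0:
        return RescueReport({m: None for m in METRIC_NAMES}, 0, n_images)
    rates = {m: float(1.0 - sub[f"outlier_{m}"].mean()) for m in METRIC_NAMES}
    return RescueReport(rates, n_hr, n_images)


# ---------------------------------------------------------------------------
# Ensemble gain


def ensemble_gain(records: pd.DataFrame, ensemble_source: str = "ensemble",
                  granularity: str = "image") -> pd.DataFrame:
    """Per-image (or per-organ mean) ensemble gains g = L_ens − L_ref.

    Losses are the Dice loss 1−DSC, RVD, ASSD and MSSD.  For each loss the
    output carries ``<loss>_ens``, ``<loss>_mean``, ``<loss>_worst`` (the
    mean and max over the single models) and the gains ``g_mean_<loss>``
    and ``g_worst_<loss>``; negative gain means the ensemble improved on
    the reference.
    """
    if granularity not in ("image", "organ"):
        raise ValueError(f"granularity must be 'image' or 'organ', got {granularity!r}")
    df = records.copy()
    df["dice_loss"] = 1.0 - df["dsc"]
    df = df.rename(columns={"assd_mm": "assd", "mssd_mm": "mssd"})
    rows = []
    for (organ, image_id), grp in df.groupby(["organ", "image_id"], sort=True):
        ens = grp[grp["source_id"] == ensemble_source]
        models = grp[~(grp["source_id"] == ensemble_source)]
        if ens.empty:
            raise ValueError(f"missing ensemble record ({ensemble_source!r}) "
                             f"for organ={organ!r}, image={image_id!r}")
        if models.empty:
            raise ValueError(f"no single-model records for organ={organ!r}, "
                             f"image={image_id!r}")
        row: dict[str, object] = {"organ": organ, "image_id": image_id}
        for loss in LOSS_COLUMNS:
            l_ens = float(ens[loss].iloc[0])
            l_mean = float(models[loss].mean())
            l_worst = float(models[loss].max())
            row[f"{loss}_ens"] = l_ens
            row[f"{loss}_mean"] = l_mean
            row[f"{loss}_worst"] = l_worst
            row[f"{loss}_sd"] = float(models[loss].std(ddof=1)) if len(models) > 1 else 0.0
            row[f"g_mean_{loss}"] = l_ens - l_mean
            row[f"g_worst_{loss}"] = l_ens - l_worst
        rows.append(row)
    gains = pd.DataFrame(rows)
    if granularity == "organ":
        gains = gains.drop(columns="image_id").groupby("organ", sort=True).mean().reset_index()
    return gains


# ---------------------------------------------------------------------------
# York line fit (errors in both coordinates)


@dataclass(frozen=True)
class LineFit:
    """Straight-line fit y = intercept + slope·x with parameter standard
    deviations from the York variance expressions."""

    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    iterations: int
    converged: bool


def york_fit(x: Sequence[float], y: Sequence[float],
             sx: Sequence[float], sy: Sequence[float],
             tol: float = 1e-10, max_iter: int = 200) -> LineFit:
    """Best straight line through points with known uncertainties in both
    coordinates (zero x–y error correlation).

    Minimises Σ_i W_i(b) (y_i − a − b x_i)² with W_i = 1/(sy_i² + b² sx_i²),
    iterating the slope from the ordinary-least-squares start until the
    slope change falls below ``tol``.  With sx ≡ 0 and constant sy this is
    exactly ordinary least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sx = np.asarray(sx, dtype=float)
    sy = np.asarray(sy, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"york_fit needs at least 3 points, got {n}")
    if x.shape != y.shape or x.shape != sx.shape or x.shape != sy.shape:
        raise ValueError("x, y, sx, sy must have equal length")
    if np.any(sx < 0) or np.any(sy < 0):
        raise ValueError("uncertainties must be non-negative")
    if np.any((sx == 0) & (sy == 0)):
        raise ValueError("every point needs sx > 0 or sy > 0 (weights degenerate)")

    # OLS start
    b = float(np.polyfit(x, y, 1)[0]) if np.ptp(x) > 0 else 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W = 1.0 / (sy**2 + b**2 * sx**2)
        xbar = float((W * x).sum() / W.sum())
        ybar = float((W * y).sum() / W.sum())
        U = x - xbar
        V = y - ybar
        beta = W * (U * sy**2 + b * V * sx**2)
        denom = float((W * beta * U).sum())
        if denom == 0.0:
            raise ValueError("degenerate York system: no x variation under the weights")
        b_new = float((W * beta * V).sum() / denom)
        if abs(b_new - b) < tol:
            b = b_new
            converged = True
            break
        b = b_new

    W = 1.0 / (sy**2 + b**2 * sx**2)
    xbar = float((W * x).sum() / W.sum())
    ybar = float((W * y).sum() / W.sum())
    a = ybar - b * xbar
    beta = W * ((x - xbar) * sy**2 + b * (y - ybar) * sx**2)
    x_adj = xbar + beta
    xbar_adj = float((W * x_adj).sum() / W.sum())
    u = x_adj - xbar_adj
    var_b = 1.0 / float((W * u**2).sum())
    var_a = 1.0 / float(W.sum()) + xbar_adj**2 * var_b
    return LineFit(b, a, math.sqrt(var_b), math.sqrt(var_a), it, converged)


# ---------------------------------------------------------------------------
# Ensemble-size subsampling


def _draw_subsets(J: int, size: int, n_rep: int,
                  rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Up to ``n_rep`` *distinct* model subsets of the given size, uniform
    without replacement; all of them when fewer than n_rep exist."""
    total = comb(J, size)
    if total <= n_rep:
        return list(combinations(range(J), size))
    subsets: set[tuple[int, ...]] = set()
    while len(subsets) < n_rep:
        subsets.add(tuple(sorted(rng.choice(J, size=size, replace=False).tolist())))
    return sorted(subsets)


def subsample_ensembles(
    model_masks_per_image: Sequence[Sequence[BinaryMask]],
    references: Sequence[BinaryMask],
    sizes: Sequence[int],
    n_rep: int = 10,
    seed: int = 0,
    p_thr: float = 0.35,
    fuse: Callable[[Sequence[BinaryMask]], BinaryMask] | None = None,
    image_ids: Sequence[str] | None = None,
    organ: str = "",
    include_surface: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Metrics of ensembles rebuilt from random model subsets.

    For each requested size, up to ``n_rep`` distinct subsets of model
    indices are drawn uniformly without replacement (the same subsets are
    applied to every image, mirroring subsampling of trained models).
    Each subset is fused — averaging + thresholding at ``p_thr`` by
    default, or a custom ``fuse`` callable — and evaluated against the
    references.  Fully reproducible from ``seed``.

    Returns ``(records, summary)``: per (size, rep, image) metric rows,
    and per-size mean and sd over reps of the per-rep image means.
    """
    J = len(model_masks_per_image[0])
    if any(len(m) != J for m in model_masks_per_image):
        raise ValueError("all images must carry the same number of model masks")
    for size in sizes:
        if not 1 <= size <= J:
            raise ValueError(f"subsample size {size} outside [1, {J}]")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if image_ids is None:
        image_ids = [f"img_{i:03d}" for i in range(len(references))]
    if fuse is None:
        fuse = lambda masks: fuse_average(masks, p_thr)  # noqa: E731

    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep, subset in enumerate(_draw_subsets(J, int(size), n_rep, rng)):
            for iid, masks, ref in zip(image_ids, model_masks_per_image, references):
                fused = fuse([masks[j] for j in subset])
                rec = evaluate(fused, ref, organ=organ, image_id=str(iid),
                               source_id=f"subset_{size}_{rep}",
                               include_surface=include_surface)
                rows.append({"size": int(size), "rep": rep,
                             "subset": ",".join(map(str, subset)),
                             "organ": organ, "image_id": str(iid),
                             "dsc": rec.dsc, "rvd": rec.rvd,
                             "assd_mm": rec.assd_mm, "mssd_mm": rec.mssd_mm,
                             "surface_defined": rec.surface_defined})
    records = pd.DataFrame(rows)

    per_rep = records.groupby(["size", "rep"])[
        ["dsc", "rvd", "assd_mm", "mssd_mm"]].mean().reset_index()
    summary = per_rep.groupby("size").agg(
        n_rep=("rep", "size"),
        dsc_mean=("dsc", "mean"), dsc_sd=("dsc", "std"),
        rvd_mean=("rvd", "mean"), rvd_sd=("rvd", "std"),
        assd_mean=("assd_mm", "mean"), assd_sd=("assd_mm", "std"),
        mssd_mean=("mssd_mm", "mean"), mssd_sd=("mssd_mm", "std"),
    ).reset_index()
    return records, summary
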