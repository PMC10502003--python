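"""End-to-end orchestration: simulate/load → fuse → evaluate → report.

`RunConfig` is a strictly validated (unknown keys rejected) configuration
object; `run_pipeline` executes the whole flow deterministically from
(config, seed) and writes a metrics table, the robustness report and a
run log with a config hash.  `compare_methods` evaluates several fusion
schemes on the identical image set.
"""

from __future__ import annotations

import hashlib
import json
import math
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .fusion import (apply_regression_combiner, fit_regression_combiner,
                     fuse_average, majority_vote, staple, staple_mask)
from .metrics import evaluate, records_to_frame, write_metrics_csv
from .robustness import (ensemble_gain, flag_outliers, high_risk_images,
                         outlier_boundaries, rescue_rates,
                         subsample_ensembles, york_fit)
from .synthetic import StudySpec, simulate_study, write_study
from .volumes import BinaryMask, StudyManifest, load_manifest, load_mask, save_mask

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compare_methods",
           "load_study_masks", "fuse_study"]

FusionMethod = Literal["average", "vote", "staple", "regression"]


class StudyConfig(BaseModel):
    """Synthetic-study parameters (subset of StudySpec; seeds come from
    the run seed)."""

    model_config = ConfigDict(extra="forbid")

    n_images: int = Field(default=40, ge=1)
    n_models: int = Field(default=16, ge=1)
    organ: str = "phantom"
    grid: int = Field(default=64, ge=8)
    p_spurious: float = Field(default=0.05, ge=0.0, le=1.0)
    p_dropout: float = Field(default=0.02, ge=0.0, le=1.0)


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    manifest: str | None = None          # load a study from disk ...
    study: StudyConfig = Field(default_factory=StudyConfig)  # ... or simulate one
    fusion_method: FusionMethod = "average"
    p_thr: float = Field(default=0.35, gt=0.0, le=1.0)
    staple_p_thr: float = Field(default=0.5, gt=0.0, le=1.0)
    percentile: float = Field(default=0.05, gt=0.0, le=0.5)
    subsample_sizes: tuple[int, ...] = ()
    n_rep: int = Field(default=10, ge=1)
    seed: int = 0
    out_dir: str | None = None
    write_masks: bool = False

    @field_validator("subsample_sizes")
    @classmethod
    def _positive_sizes(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        if any(s < 1 for s in v):
            raise ValueError("subsample sizes must be >= 1")
        return v


class PipelineResult:
    """In-memory results of one pipeline run."""

    def __init__(self, metrics: pd.DataFrame, report: dict,
                 out_dir: Path | None) -> None:
        self.metrics = metrics
        self.report = report
        self.out_dir = out_dir


def load_study_masks(manifest: StudyManifest, root: str | Path = "."
                     ) -> tuple[list[list[BinaryMask]], list[BinaryMask],
                                list[str], str]:
    """Materialise a manifest: (model masks per image, references,
    image ids, organ)."""
    root = Path(root)

    def _resolve(p: str) -> Path:
        cand = root / p
        return cand if cand.exists() else Path(p)

    model_masks, references, ids = [], [], []
    organ = manifest.images[0].organ if manifest.images else ""
    for rec in manifest.images:
        references.append(load_mask(_resolve(rec.reference_path), label="reference"))
        model_masks.append([load_mask(_resolve(p), label=mid)
                            for mid, p in rec.model_paths])
        ids.append(rec.image_id)
    return model_masks, references, ids, organ


def fuse_study(model_masks_per_image: Sequence[Sequence[BinaryMask]],
               references: Sequence[BinaryMask], method: FusionMethod,
               p_thr: float = 0.35, staple_p_thr: float = 0.5
               ) -> list[BinaryMask]:
    """Fuse each image's candidates with the chosen scheme.

    The regression combiner is fitted on the study itself (all images)
    before selecting per image; averaging/voting/STAPLE are per-image.
    """
    if method == "average":
        return [fuse_average(m, p_thr) for m in model_masks_per_image]
    if method == "vote":
        return [majority_vote(m) for m in model_masks_per_image]
    if method == "staple":
        out = []
        for masks in model_masks_per_image:
            W, _ = staple(masks)
            out.append(staple_mask(W, staple_p_thr))
        return out
    if method == "regression":
        combiner = fit_regression_combiner(
            [(list(m), ref) for m, ref in zip(model_masks_per_image, references)])
        return [apply_regression_combiner(combiner, list(m))[1]
                for m in model_masks_per_image]
    raise ValueError(f"unknown fusion method {method!r}")


def _study_spec_from_config(cfg: RunConfig) -> StudySpec:
    from .synthetic import ModelProfile, PhantomSpec

    g = cfg.study.grid
    scale = g / 64.0
    phantom = PhantomSpec(grid_shape=(g, g, g),
                          semi_axes=(16.0 * scale, 14.0 * scale, 12.0 * scale))
    profile = ModelProfile(p_spurious=cfg.study.p_spurious,
                           p_dropout=cfg.study.p_dropout,
                           translation_max_voxels=0.75 * scale,
                           spurious_min_distance_mm=20.0 * scale,
                           spurious_volume_range=(60.0 * scale**3,
                                                  400.0 * scale**3))
    return StudySpec(n_images=cfg.study.n_images, n_models=cfg.study.n_models,
                     organ=cfg.study.organ, phantom=phantom,
                     profiles=tuple(profile for _ in range(cfg.study.n_models)),
                     master_seed=cfg.seed)


def run_pipeline(config: RunConfig | dict) -> PipelineResult:
    """Execute simulate/load → fuse → evaluate → robustness report.

    With an ``out_dir`` the metrics CSV, the robustness JSON, consensus
    masks (optional) and a log recording versions, the config hash and the
    seed are written; the run is idempotent given (config, seed).
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig(**config)
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    stage = "input"
    try:
        if cfg.manifest:
            manifest = load_manifest(cfg.manifest)
            model_masks, references, image_ids, organ = load_study_masks(
                manifest, Path(cfg.manifest).parent)
        else:
            study = simulate_study(_study_spec_from_config(cfg))
            model_masks = study.model_masks_per_image
            references = study.references
            image_ids = study.image_ids
            organ = study.spec.organ
            if out_dir and cfg.write_masks:
                write_study(study, out_dir / "study")

        stage = "fuse"
        fused = fuse_study(model_masks, references, cfg.fusion_method,
                           cfg.p_thr, cfg.staple_p_thr)
        if out_dir and cfg.write_masks:
            for iid, mask in zip(image_ids, fused):
                save_mask(mask, out_dir / "consensus" / f"{iid}_{cfg.fusion_method}.nii")

        stage = "evaluate"
        records = []
        model_ids = [m.label or f"model_{j}" for j, m in enumerate(model_masks[0])]
        for iid, masks, ref, ens in zip(image_ids, model_masks, references, fused):
            for mid, mask in zip(model_ids, masks):
                records.append(evaluate(mask, ref, organ=organ, image_id=iid,
                                        source_id=mid))
            records.append(evaluate(ens, ref, organ=organ, image_id=iid,
                                    source_id="ensemble"))
        metrics = records_to_frame(records)

        stage = "robustness"
        report = robustness_report(metrics, cfg.percentile)
        if cfg.subsample_sizes:
            _, summary = subsample_ensembles(
                model_masks, references, list(cfg.subsample_sizes),
                n_rep=cfg.n_rep, seed=cfg.seed, p_thr=cfg.p_thr,
                image_ids=image_ids, organ=organ)
            report["subsample_summary"] = summary.to_dict(orient="records")

        stage = "write"
        if out_dir:
            write_metrics_csv(metrics, out_dir / "metrics.csv")
            with open(out_dir / "robustness.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
                fh.write("\n")
            _write_log(out_dir / "run.log", cfg)
        return PipelineResult(metrics, report, out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def robustness_report(metrics: pd.DataFrame, percentile: float = 0.05) -> dict:
    """Boundaries, high-risk images, rescue rates and mean/worst gain fits
    from a metric table containing single-model and 'ensemble' rows."""
    model_rows = metrics[metrics["source_id"] != "ensemble"]
    ens_rows = metrics[metrics["source_id"] == "ensemble"]
    boundaries = outlier_boundaries(model_rows, percentile)
    flagged_models = flag_outliers(model_rows, boundaries)
    flagged_ens = flag_outliers(ens_rows, boundaries)
    risky = high_risk_images(flagged_models)
    rescue = rescue_rates(risky, flagged_ens)
    gains = ensemble_gain(metrics)

    fits = {}
    if len(gains) >= 3:
        for loss in ("dice_loss", "mssd"):
            sd = gains[f"{loss}_sd"].to_numpy()
            sd = np.where(sd > 0, sd, np.nanmax(sd) if np.nanmax(sd) > 0 else 1.0)
            try:
                fit = york_fit(gains[f"{loss}_mean"], gains[f"g_mean_{loss}"],
                               sd, sd)
                fits[loss] = {"slope": fit.slope, "intercept": fit.intercept,
                              "slope_sd": fit.slope_sd,
                              "intercept_sd": fit.intercept_sd,
                              "converged": fit.converged}
            except ValueError:
                fits[loss] = None
    return {
        "boundaries": [asdict(b) for b in boundaries],
        "high_risk_images": {k: sorted(v) for k, v in risky.items()},
        "n_high_risk": rescue.n_high_risk,
        "n_images": rescue.n_images,
        "high_risk_fraction": rescue.high_risk_fraction,
        "rescue_rates": dict(rescue.rates),
        "gain_fits": fits,
    }


def compare_methods(model_masks_per_image: Sequence[Sequence[BinaryMask]],
                    references: Sequence[BinaryMask],
                    methods: Sequence[FusionMethod],
                    p_thr: float = 0.35, staple_p_thr: float = 0.5
                    ) -> pd.DataFrame:
    """Mean ± sd-of-mean of each metric per fusion method, on the
    identical image set.  With a single image the sd of the mean is
    reported as NaN (undefined).

    The returned frame carries Kruskal–Wallis p-values across methods per
    metric (are the per-image metric distributions compatible with one
    shared distribution?) in ``table.attrs["kruskal_p"]``; computed with
    the standard scipy routine, NaN when degenerate.
    """
    if len(methods) < 2:
        raise ValueError("compare_methods needs at least 2 fusion methods")
    rows = []
    per_method_values: dict[str, dict[str, np.ndarray]] = {}
    for method in methods:
        fused = fuse_study(model_masks_per_image, references, method,
                           p_thr, staple_p_thr)
        recs = [evaluate(f, r, source_id=method)
                for f, r in zip(fused, references)]
        n = len(recs)
        row: dict[str, object] = {"method": method, "n_images": n}
        per_method_values[method] = {}
        for name, attr in (("dsc", "dsc"), ("rvd", "rvd"),
                           ("assd", "assd_mm"), ("mssd", "mssd_mm")):
            vals = np.array([getattr(r, attr) for r in recs], dtype=float)
            per_method_values[method][name] = vals
            row[f"{name}_mean"] = float(np.nanmean(vals))
            row[f"{name}_sdom"] = (float(np.nanstd(vals, ddof=1) / math.sqrt(n))
                                   if n > 1 else math.nan)
        rows.append(row)
    table = pd.DataFrame(rows)

    from scipy import stats as _stats
    kruskal_p = {}
    for name in ("dsc", "rvd", "assd", "mssd"):
        groups = [per_method_values[m][name] for m in methods]
        try:
            kruskal_p[name] = float(_stats.kruskal(*groups).pvalue)
        except ValueError:  # all values identical across groups
            kruskal_p[name] = math.nan
    table.attrs["kruskal_p"] = kruskal_p
    return table


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_log(path: Path, cfg: RunConfig) -> None:
    blob = json.dumps(cfg.model_dump(), sort_keys=True)
    cfg_hash = hashlib.sha256(blob.encode()).hexdigest()[:16]
    from importlib.metadata import version
    try:
        pkg_version = version("segensemble")
    except Exception:
        pkg_version = "unknown"
    lines = [
        f"segensemble {pkg_version}",
        f"python {platform.python_version()}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
        f"seed {cfg.seed}",
        f"config_hash {cfg_hash}",
        f"config {blob}",
    ]
    path.write_text("\n".join(lines) + "\n")
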