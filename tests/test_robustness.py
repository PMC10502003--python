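"""Outlier boundaries, high-risk images, rescue rates, gains, York fits
and ensemble-size subsampling."""

import math

import numpy as np
import pandas as pd
import pytest

import segensemble as se
from segensemble.robustness import _draw_subsets

from conftest import random_mask, sorted_quantile


def frame(rows):
    base = {"organ": "o", "image_id": "i0", "source_id": "m0",
            "dsc": 0.9, "rvd": 0.05, "assd_mm": 1.0, "mssd_mm": 3.0,
            "surface_defined": True}
    return pd.DataFrame([{**base, **r} for r in rows])


def model_frame(rng, n_images=10, n_models=5, organ="o"):
    rows = []
    for i in range(n_images):
        for j in range(n_models):
            rows.append({"organ": organ, "image_id": f"i{i}",
                         "source_id": f"m{j}",
                         "dsc": rng.uniform(0.6, 1.0),
                         "rvd": rng.uniform(0, 0.3),
                         "assd_mm": rng.uniform(0, 3),
                         "mssd_mm": rng.uniform(0, 20),
                         "surface_defined": True})
    return pd.DataFrame(rows)


class TestOutlierBoundaries:
    def test_quantile_matches_sort_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            df = model_frame(rng, n_images=n, n_models=1)
            bounds = {b.metric: b for b in se.outlier_boundaries(df, 0.05)}
            assert bounds["dsc"].cutoff == pytest.approx(
                sorted_quantile(df["dsc"], 0.05), abs=1e-12)
            assert bounds["mssd"].cutoff == pytest.approx(
                sorted_quantile(df["mssd_mm"], 0.95), abs=1e-12)
            assert bounds["dsc"].direction == "below"
            assert bounds["mssd"].direction == "above"

    def test_flags_match_sorted_oracle(self, rng):
        df = model_frame(rng, n_images=20, n_models=1)
        bounds = se.outlier_boundaries(df, 0.05)
        flagged = se.flag_outliers(df, bounds)
        cutoff = sorted_quantile(df["dsc"], 0.05)
        assert flagged["outlier_dsc"].tolist() == (df["dsc"] < cutoff).tolist()

    def test_all_identical_values_yield_no_outliers(self):
        df = frame([{"image_id": f"i{k}"} for k in range(10)])
        flagged = se.flag_outliers(df, se.outlier_boundaries(df))
        assert not flagged["outlier_any"].any()

    def test_max_of_increasing_sample_flagged_above(self, rng):
        vals = np.arange(25, dtype=float)
        df = frame([{"image_id": f"i{k}", "mssd_mm": v}
                    for k, v in enumerate(vals)])
        flagged = se.flag_outliers(df, se.outlier_boundaries(df))
        assert flagged.loc[flagged["mssd_mm"].idxmax(), "outlier_mssd"]

    def test_value_exactly_at_cutoff_not_outlier(self):
        b = se.OutlierBoundary("o", "mssd", 0.05, 10.0, "above")
        assert not b.is_outlier(10.0)
        assert b.is_outlier(10.0 + 1e-9)
        b2 = se.OutlierBoundary("o", "dsc", 0.05, 0.7, "below")
        assert not b2.is_outlier(0.7)
        assert b2.is_outlier(0.7 - 1e-9)

    def test_degenerate_capped_record_flagged(self, rng):
        df = model_frame(rng, n_images=30, n_models=2)
        cap = 64 * math.sqrt(3)  # physical diagonal of a 64^3 1 mm grid
        bad = {"organ": "o", "image_id": "i99", "source_id": "m0",
               "dsc": 0.0, "rvd": 1.0, "assd_mm": cap, "mssd_mm": cap,
               "surface_defined": False}
        df = pd.concat([df, pd.DataFrame([bad])], ignore_index=True)
        flagged = se.flag_outliers(df, se.outlier_boundaries(df))
        row = flagged[flagged["image_id"] == "i99"].iloc[0]
        assert row["outlier_mssd"] and row["outlier_any"]

    def test_flags_invariant_to_record_order(self, rng):
        df = model_frame(rng)
        bounds = se.outlier_boundaries(df)
        f1 = se.flag_outliers(df, bounds)
        shuffled = df.sample(frac=1, random_state=1)
        f2 = se.flag_outliers(shuffled, bounds).sort_index()
        assert f1["outlier_any"].tolist() == f2["outlier_any"].tolist()

    def test_per_model_pooling_mode(self, rng):
        df = model_frame(rng)
        bounds = se.outlier_boundaries(df, pooling="per_model")
        assert {b.source_id for b in bounds} == {f"m{j}" for j in range(5)}

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            se.outlier_boundaries(pd.DataFrame())

    def test_missing_boundary_raises(self, rng):
        df = model_frame(rng)
        with pytest.raises(KeyError, match="boundary"):
            se.flag_outliers(df, [])


class TestHighRiskAndRescue:
    def _flagged(self, rng, outlier_cells):
        df = model_frame(rng, n_images=8, n_models=3)
        for col in ("outlier_dsc", "outlier_rvd", "outlier_assd",
                    "outlier_mssd"):
            df[col] = False
        for (img, model, metric) in outlier_cells:
            sel = (df["image_id"] == img) & (df["source_id"] == model)
            df.loc[sel, f"outlier_{metric}"] = True
        df["outlier_any"] = df[[c for c in df.columns
                                if c.startswith("outlier_")]].any(axis=1)
        return df

    def test_no_flags_no_high_risk(self, rng):
        assert se.high_risk_images(self._flagged(rng, [])) == {}

    def test_single_flag_defines_high_risk(self, rng):
        flagged = self._flagged(rng, [("i3", "m1", "mssd")])
        assert se.high_risk_images(flagged) == {"o": {"i3"}}

    def test_rescue_arithmetic(self, rng):
        flagged_models = self._flagged(
            rng, [(f"i{k}", "m0", "mssd") for k in range(5)])
        high_risk = se.high_risk_images(flagged_models)
        ens = self._flagged(rng, [])
        ens = ens[ens["source_id"] == "m0"].copy()
        ens["source_id"] = "ensemble"
        ens.loc[ens["image_id"] == "i0", "outlier_assd"] = True
        report = se.rescue_rates(high_risk, ens)
        assert report.rates["assd"] == pytest.approx(4 / 5)
        assert report.rates["mssd"] == 1.0
        assert report.n_high_risk == 5
        assert report.high_risk_fraction == pytest.approx(5 / 8)

    def test_unflagged_ensemble_rescues_everything(self, rng):
        flagged_models = self._flagged(rng, [("i1", "m2", "dsc")])
        ens = self._flagged(rng, [])
        report = se.rescue_rates(se.high_risk_images(flagged_models), ens)
        assert all(v == 1.0 for v in report.rates.values())

    def test_empty_high_risk_set_is_null_result(self, rng):
        ens = self._flagged(rng, [])
        report = se.rescue_rates({}, ens)
        assert all(v is None for v in report.rates.values())
        assert report.n_high_risk == 0


class TestEnsembleGain:
    def _records(self, ens_dsc, model_dscs):
        rows = [{"source_id": "ensemble", "dsc": ens_dsc}]
        rows += [{"source_id": f"m{j}", "dsc": d}
                 for j, d in enumerate(model_dscs)]
        return frame(rows)

    def test_zero_gain_when_ensemble_equals_mean(self):
        gains = se.ensemble_gain(self._records(0.8, [0.7, 0.9]))
        assert gains["g_mean_dice_loss"].iloc[0] == pytest.approx(0.0)

    def test_sign_convention(self):
        # <DL> = 0.25, DL_ens = 0.22 -> g = -0.03 (improvement)
        gains = se.ensemble_gain(self._records(0.78, [0.70, 0.80]))
        assert gains["g_mean_dice_loss"].iloc[0] == pytest.approx(-0.03)

    def test_worst_reference(self):
        gains = se.ensemble_gain(self._records(0.9, [0.6, 0.85]))
        assert gains["dice_loss_worst"].iloc[0] == pytest.approx(0.4)
        assert gains["g_worst_dice_loss"].iloc[0] == pytest.approx(0.1 - 0.4)

    def test_sorted_worst_gain_is_monotone(self, rng):
        df = model_frame(rng, n_images=12, n_models=4)
        ens = df[df["source_id"] == "m0"].copy()
        ens["source_id"] = "ensemble"
        ens["dsc"] = 0.95
        gains = se.ensemble_gain(pd.concat([df, ens], ignore_index=True))
        ordered = gains.sort_values("g_worst_dice_loss", ascending=False)
        assert np.all(np.diff(ordered["g_worst_dice_loss"]) <= 1e-12)

    def test_missing_ensemble_record(self, rng):
        df = model_frame(rng, n_images=2, n_models=2)
        with pytest.raises(ValueError, match="missing ensemble"):
            se.ensemble_gain(df)


def york_objective(x, y, sx, sy, a, b):
    W = 1.0 / (sy**2 + b**2 * sx**2)
    return float((W * (y - a - b * x) ** 2).sum())


def grid_minimise_york(x, y, sx, sy, b0, a0, half=1.0, levels=6, n=41):
    """Brute-force nested grid search over (intercept, slope)."""
    best = (a0, b0)
    for _ in range(levels):
        a_grid = np.linspace(best[0] - half, best[0] + half, n)
        b_grid = np.linspace(best[1] - half, best[1] + half, n)
        vals = [(york_objective(x, y, sx, sy, a, b), a, b)
                for a in a_grid for b in b_grid]
        _, a_best, b_best = min(vals)
        best = (a_best, b_best)
        half /= 10.0
    return best


class TestYorkFit:
    def test_reduces_to_ols_when_x_exact(self, rng):
        x = rng.uniform(0, 10, 15)
        y = 1.5 * x - 2 + rng.normal(0, 1, 15)
        fit = se.york_fit(x, y, np.zeros(15), np.full(15, 0.7))
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_exact_line_any_errors(self, rng):
        x = np.linspace(0, 5, 12)
        fit = se.york_fit(x, 2 * x + 1, rng.uniform(0.1, 1, 12),
                          rng.uniform(0.1, 1, 12))
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.converged

    def test_matches_grid_search_oracle(self, rng):
        n = 25
        x_true = rng.uniform(0, 10, n)
        sx = rng.uniform(0.05, 0.5, n)
        sy = rng.uniform(0.1, 1.0, n)
        x = x_true + rng.normal(0, sx)
        y = 0.8 * x_true + 3 + rng.normal(0, sy)
        fit = se.york_fit(x, y, sx, sy)
        a_ref, b_ref = grid_minimise_york(x, y, sx, sy, fit.slope + 0.3,
                                          fit.intercept - 0.3)
        assert fit.slope == pytest.approx(b_ref, abs=1e-4)
        assert fit.intercept == pytest.approx(a_ref, abs=1e-3)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 3"):
            se.york_fit([1, 2], [1, 2], [1, 1], [1, 1])
        with pytest.raises(ValueError, match="non-negative"):
            se.york_fit([1, 2, 3], [1, 2, 3], [-1, 1, 1], [1, 1, 1])
        with pytest.raises(ValueError, match="degenerate"):
            se.york_fit([1, 2, 3], [1, 2, 3], [0, 1, 1], [0, 1, 1])


class TestSubsampleEnsembles:
    def _study(self, rng, n_images=3, J=5):
        refs = [random_mask(rng, (8, 8, 8), p=0.3) for _ in range(n_images)]
        masks = [[random_mask(rng, (8, 8, 8), p=0.3) for _ in range(J)]
                 for _ in range(n_images)]
        return masks, refs

    def test_full_size_equals_full_ensemble(self, rng):
        masks, refs = self._study(rng)
        records, summary = se.subsample_ensembles(masks, refs, [5], n_rep=10,
                                                  seed=1)
        assert records["rep"].nunique() == 1  # only one distinct subset
        full = [se.evaluate(se.fuse_average(m), r)
                for m, r in zip(masks, refs)]
        assert summary["dsc_mean"].iloc[0] == pytest.approx(
            np.mean([f.dsc for f in full]))

    def test_reproducible_from_seed(self, rng):
        masks, refs = self._study(rng)
        r1, s1 = se.subsample_ensembles(masks, refs, [2, 3], n_rep=4, seed=7)
        r2, s2 = se.subsample_ensembles(masks, refs, [2, 3], n_rep=4, seed=7)
        pd.testing.assert_frame_equal(r1, r2)
        assert r1["subset"].tolist() == r2["subset"].tolist()

    def test_subsets_distinct(self):
        rng = np.random.default_rng(3)
        subsets = _draw_subsets(10, 4, 10, rng)
        assert len(subsets) == len(set(subsets)) == 10
        assert all(len(s) == 4 for s in subsets)

    def test_size_larger_than_ensemble_rejected(self, rng):
        masks, refs = self._study(rng)
        with pytest.raises(ValueError, match="outside"):
            se.subsample_ensembles(masks, refs, [6], seed=0)
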