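"""Predictor extraction, model selection, cross-validation, and map prediction."""
import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from larchfire.rasters import AlignmentError, RasterGrid
from larchfire.spatial import (
    SpatialModel,
    cross_validate,
    extract_plot_predictors,
    mc_spatial_uncertainty,
    predict_map,
    select_model,
)
from larchfire.types import ValidationError


def _grid(values, x0=0.0, y0=None, px=30.0):
    values = np.asarray(values, dtype=float)
    if y0 is None:
        y0 = values.shape[0] * px
    return RasterGrid(values, x_origin=x0, y_origin=y0, pixel_size=px, crs="X")


class TestExtraction:
    def test_square_inside_one_pixel(self):
        g = _grid(np.arange(16).reshape(4, 4), px=60.0)
        plots = pd.DataFrame({"plot_id": ["p"], "x": [90.0], "y": [90.0]})
        out = extract_plot_predictors({"b": g}, plots, square_size=30.0)
        # pixel row 2, col 1 -> value 9
        assert out["b"].iloc[0] == pytest.approx(9.0)

    def test_equal_split_across_two_pixels(self):
        g = _grid([[1.0, 3.0]], px=30.0)
        plots = pd.DataFrame({"plot_id": ["p"], "x": [30.0], "y": [15.0]})
        out = extract_plot_predictors({"b": g}, plots, square_size=30.0)
        assert out["b"].iloc[0] == pytest.approx(2.0)

    def test_75_25_weighted_mean(self):
        g = _grid([[0.0, 4.0]], px=30.0)
        # square center at x=22.5: covers x 7.5..37.5 -> 22.5 m of pixel 0, 7.5 m of pixel 1
        plots = pd.DataFrame({"plot_id": ["p"], "x": [22.5], "y": [15.0]})
        out = extract_plot_predictors({"b": g}, plots, square_size=30.0)
        assert out["b"].iloc[0] == pytest.approx(1.0)

    def test_nodata_excluded_from_weighting(self):
        g = _grid([[np.nan, 4.0]], px=30.0)
        plots = pd.DataFrame({"plot_id": ["p"], "x": [30.0], "y": [15.0]})
        out = extract_plot_predictors({"b": g}, plots, square_size=30.0)
        assert out["b"].iloc[0] == pytest.approx(4.0)

    def test_all_nodata_warns_and_is_missing(self):
        g = _grid([[np.nan]], px=30.0)
        plots = pd.DataFrame({"plot_id": ["p"], "x": [15.0], "y": [15.0]})
        with pytest.warns(UserWarning, match="no valid"):
            out = extract_plot_predictors({"b": g}, plots, square_size=30.0)
        assert np.isnan(out["b"].iloc[0])


def _linear_frame(n=200, seed=0, noise=0.0, slope2=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
    df["y"] = 1.5 + 2.0 * df["x1"] + slope2 * df["x2"] + noise * rng.normal(size=n)
    return df


class TestSelectModel:
    def test_noiseless_exact_recovery(self):
        df = _linear_frame(noise=0.0, slope2=-0.7)
        m = select_model(df, "y", {"s": ["x1", "x2"]})
        assert m.coef["x1"] == pytest.approx(2.0, abs=1e-9)
        assert m.coef["x2"] == pytest.approx(-0.7, abs=1e-9)
        assert m.resid_sd == pytest.approx(0.0, abs=1e-8)

    def test_informative_kept_noise_dropped(self):
        hits = 0
        for seed in range(20):
            df = _linear_frame(seed=seed, noise=1.0)
            m = select_model(df, "y", {"s": ["x1", "x2"]})
            hits += ("x1" in m.predictors) and ("x2" not in m.predictors)
        assert hits >= 18

    def test_single_significant_predictor(self):
        df = _linear_frame(noise=0.5).drop(columns="x2")
        m = select_model(df, "y", {"s": ["x1"]})
        assert m.predictors == ["x1"]

    def test_no_signal_gives_flagged_intercept_only(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x1": rng.normal(size=50), "y": rng.normal(size=50)})
        m = select_model(df, "y", {"s": ["x1"]})
        assert m.intercept_only or m.predictors == []


class TestCrossValidate:
    def test_noiseless_linear_gives_r2_one(self):
        df = _linear_frame(noise=0.0)
        assert cross_validate(df, "y", ["x1"], reps=5, seed=0) == pytest.approx(1.0)

    def test_pure_noise_r2_near_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x1": rng.normal(size=200), "y": rng.normal(size=200)})
        assert cross_validate(df, "y", ["x1"], reps=20, seed=0) <= 0.05

    def test_seed_determinism(self):
        df = _linear_frame(noise=0.8)
        a = cross_validate(df, "y", ["x1"], reps=10, seed=5)
        b = cross_validate(df, "y", ["x1"], reps=10, seed=5)
        assert a == b

    def test_too_few_rows(self):
        df = _linear_frame(n=5)
        with pytest.raises(ValidationError, match="smaller"):
            cross_validate(df, "y", ["x1"], k=10)


def _model(const=1.0, **slopes):
    return SpatialModel(
        predictors=list(slopes), coef={"const": const, **slopes}, resid_sd=0.0,
        r2=1.0, adj_r2=1.0,
    )


class TestPredictMap:
    def test_intercept_only_constant_map(self):
        g = _grid(np.zeros((4, 4)))
        perim = box(0, 0, 120, 120)
        out = predict_map(_model(const=1.0), {"b": g}, perim)
        assert np.allclose(out.values[~np.isnan(out.values)], 1.0)

    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(3)
        g = _grid(rng.normal(size=(5, 5)))
        truth = 0.5 + 2.0 * g.values
        out = predict_map(_model(const=0.5, b=2.0), {"b": g}, box(0, 0, 150, 150))
        assert np.allclose(out.values, truth)

    def test_empty_mask_warns(self):
        g = _grid(np.zeros((3, 3)))
        far = Polygon([(1e6, 1e6), (1e6 + 1, 1e6), (1e6, 1e6 + 1)])
        with pytest.warns(UserWarning, match="every pixel"):
            out = predict_map(_model(const=1.0), {"b": g}, far)
        assert np.all(np.isnan(out.values))

    def test_misaligned_rasters_raise(self):
        g1 = _grid(np.zeros((3, 3)))
        g2 = _grid(np.zeros((3, 3)), x0=15.0)
        with pytest.raises(AlignmentError):
            predict_map(_model(const=0.0, a=1.0, b=1.0), {"a": g1, "b": g2}, box(0, 0, 90, 90))

    def test_outside_perimeter_is_nodata_not_zero(self):
        g = _grid(np.zeros((4, 4)))
        out = predict_map(_model(const=2.0), {"b": g}, box(0, 0, 60, 120))
        assert np.isnan(out.values[0, 3])
        assert out.values[0, 0] == pytest.approx(2.0)


class TestMcSpatialUncertainty:
    def _inputs(self, n_plots=15, seed=0):
        rng = np.random.default_rng(seed)
        g = _grid(rng.normal(size=(6, 6)))
        df = pd.DataFrame(
            {
                "plot_id": [f"p{i}" for i in range(n_plots)],
                "b": rng.normal(size=n_plots),
                "comb_trees": rng.uniform(0.3, 0.6, n_plots),
                "comb_debris": rng.uniform(0.05, 0.2, n_plots),
                "cb": rng.uniform(1.5, 3.0, n_plots),
            }
        )
        return g, df, box(0, 0, 180, 180)

    def test_degenerate_ensemble_zero_sd(self):
        g, df, perim = self._inputs()
        df["ct"] = 2.5  # constant response -> zero residual SD on refit
        df["comb_trees"], df["comb_debris"], df["cb"] = 0.5, 0.1, 1.9
        sds = pd.DataFrame({"sd_trees": 0.0, "sd_debris": 0.0, "sd_belowground": 0.0},
                           index=df.index)
        m = _model(const=2.5)
        out = mc_spatial_uncertainty(df, sds, m, {"b": g}, perim, n_sims=40, seed=1)
        assert np.nanmax(out.values) == pytest.approx(0.0, abs=1e-6)

    def test_intercept_only_pixel_sd_approaches_residual_sd(self):
        g, df, perim = self._inputs(seed=4)
        rng = np.random.default_rng(9)
        sigma = 0.4
        # response = constant + residual noise; plot-level SDs zero
        df["cb"] = 2.0 + rng.normal(0, sigma, len(df))
        df["comb_trees"] = 0.0
        df["comb_debris"] = 0.0
        sds = pd.DataFrame({"sd_trees": 0.0, "sd_debris": 0.0, "sd_belowground": 0.0},
                           index=df.index)
        out = mc_spatial_uncertainty(df, sds, _model(const=2.0), {"b": g}, perim,
                                     n_sims=600, seed=2)
        observed = float(np.nanmean(out.values))
        sample_sd = df["cb"].std(ddof=1)
        assert observed == pytest.approx(sample_sd, rel=0.25)

    def test_seed_determinism(self):
        g, df, perim = self._inputs(seed=6)
        sds = pd.DataFrame({"sd_trees": 0.05, "sd_debris": 0.02, "sd_belowground": 0.2},
                           index=df.index)
        m = _model(const=1.0, b=0.5)
        a = mc_spatial_uncertainty(df, sds, m, {"b": g}, perim, n_sims=30, seed=3)
        b = mc_spatial_uncertainty(df, sds, m, {"b": g}, perim, n_sims=30, seed=3)
        assert np.array_equal(a.values, b.values, equal_nan=True)
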