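"""Regression-based upscaling of plot combustion to fire-scar rasters.

Plot-level predictor values are area-weighted means of the 30 m pixels
covering each 30 m x 30 m plot square. Model selection screens each predictor
set for rank collinearity, keeps significant terms per set, and reduces the
pooled model by backward stepwise AIC; a repeated 10-fold cross validation
guards against overfitting. The selected linear model predicts combustion at
every in-perimeter pixel, and a Monte Carlo loop (plot-level combustion
perturbed by its uncertainty, model refitted, pixel residual noise added)
yields a per-pixel uncertainty map.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from shapely.geometry import Point
from shapely.prepared import prep
from sklearn.model_selection import KFold

from .drivers import screen_collinearity
from .rasters import AlignmentError, RasterGrid
from .types import ValidationError

log = logging.getLogger(__name__)


def extract_plot_predictors(
    rasters: dict[str, RasterGrid],
    plots: pd.DataFrame,
    square_size: float = 30.0,
) -> pd.DataFrame:
    """Area-weighted pixel means per plot square, one column per raster band.

    ``plots`` needs columns plot_id, x, y (square centers in the raster CRS).
    Nodata pixels are excluded from the weighting; a square entirely on
    nodata (or outside the raster) yields NaN with a warning.
    """
    out = {"plot_id": list(plots["plot_id"])}
    half = square_size / 2.0
    for band, grid in rasters.items():
        xe, ye = grid.x_edges(), grid.y_edges()  # ye decreasing
        vals = []
        for _, p in plots.iterrows():
            x0, x1 = p["x"] - half, p["x"] + half
            y0, y1 = p["y"] - half, p["y"] + half
            # interval overlaps with pixel columns / rows
            wx = np.maximum(np.minimum(x1, xe[1:]) - np.maximum(x0, xe[:-1]), 0.0)
            wy = np.maximum(np.minimum(y1, ye[:-1]) - np.maximum(y0, ye[1:]), 0.0)
            w = np.outer(wy, wx)
            valid = ~np.isnan(grid.values)
            wsum = float((w * valid).sum())
            if wsum <= 0:
                warnings.warn(
                    f"plot {p['plot_id']} has no valid {band} pixels; predictor set to NaN",
                    stacklevel=2,
                )
                vals.append(np.nan)
            else:
                vals.append(float(np.nansum(w * np.where(valid, grid.values, 0.0)) / wsum))
        out[band] = vals
    return pd.DataFrame(out)


@dataclass
class SpatialModel:
    predictors: list[str]
    coef: dict[str, float]  # includes "const"
    resid_sd: float
    r2: float
    adj_r2: float
    cv_r2: float | None = None
    intercept_only: bool = False

    def predict_frame(self, df: pd.DataFrame) -> np.ndarray:
        y = np.full(len(df), self.coef["const"])
        for p in self.predictors:
            y = y + self.coef[p] * df[p].to_numpy(dtype=float)
        return y


def _ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X) if "const" not in X.columns else X).fit()


def _fit_spatial(df: pd.DataFrame, response: str, predictors: list[str]) -> SpatialModel:
    y = df[response].to_numpy(dtype=float)
    if predictors:
        res = _ols(y, df[predictors].astype(float))
        coef = {("const" if k == "const" else k): float(v) for k, v in res.params.items()}
        dof = max(int(res.df_resid), 1)
        resid_sd = float(np.sqrt(np.sum(res.resid**2) / dof))
        return SpatialModel(
            predictors=list(predictors), coef=coef, resid_sd=resid_sd,
            r2=float(res.rsquared), adj_r2=float(res.rsquared_adj),
        )
    resid = y - y.mean()
    sd = float(np.sqrt(np.sum(resid**2) / max(len(y) - 1, 1)))
    return SpatialModel(
        predictors=[], coef={"const": float(y.mean())}, resid_sd=sd, r2=0.0, adj_r2=0.0,
        intercept_only=True,
    )


def select_model(
    df: pd.DataFrame,
    response: str,
    predictor_sets: dict[str, list[str]],
    alpha: float = 0.05,
) -> SpatialModel:
    """Per-set collinearity screen and significance filter, then backward AIC.

    Falls back to an explicitly flagged intercept-only model when no
    predictor is significant anywhere.
    """
    n = len(df)
    significant: list[str] = []
    for set_name, preds in predictor_sets.items():
        preds = [p for p in preds if p in df.columns]
        if not preds:
            continue
        retained, _ = screen_collinearity(df[preds], df[response], alpha=alpha)
        if not retained:
            continue
        if n <= len(retained) + 2:
            raise ValidationError(f"too few plots to fit predictor set {set_name!r}")
        res = _ols(df[response].to_numpy(dtype=float), df[retained].astype(float))
        for p in retained:
            if res.pvalues[p] < alpha:
                significant.append(p)

    if not significant:
        log.warning("no significant predictor in any set; returning intercept-only model")
        return _fit_spatial(df, response, [])

    # backward stepwise on AIC
    current = list(dict.fromkeys(significant))
    y = df[response].to_numpy(dtype=float)
    best_aic = _ols(y, df[current].astype(float)).aic
    improved = True
    while improved and len(current) > 1:
        improved = False
        for p in list(current):
            trial = [q for q in current if q != p]
            aic = _ols(y, df[trial].astype(float)).aic
            if aic < best_aic - 1e-9:
                best_aic = aic
                current = trial
                improved = True
                break
    return _fit_spatial(df, response, current)


def cross_validate(
    df: pd.DataFrame,
    response: str,
    predictors: list[str],
    k: int = 10,
    reps: int = 100,
    seed: int = 0,
) -> float:
    """Mean over repetitions of R^2 on pooled out-of-fold predictions."""
    n = len(df)
    if n < k:
        raise ValidationError(f"n={n} < k={k}; use a smaller number of folds")
    y = df[response].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n)] + [df[p].to_numpy(dtype=float) for p in predictors])
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(reps)
    scores = []
    for r in range(reps):
        kf = KFold(n_splits=k, shuffle=True, random_state=int(rep_seeds[r] % (2**32 - 1)))
        pred = np.empty(n)
        for train, test in kf.split(X):
            beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
            pred[test] = X[test] @ beta
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        scores.append(1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0)
    return float(np.mean(scores))


def _check_alignment(rasters: dict[str, RasterGrid]) -> RasterGrid:
    grids = list(rasters.values())
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_grid(g):
            raise AlignmentError(
                f"raster {g.band!r} is not co-registered with {ref.band!r}; no silent resampling"
            )
    return ref


def perimeter_mask(ref: RasterGrid, perimeter) -> np.ndarray:
    """Boolean in-perimeter mask from pixel-center containment in a polygon."""
    xs, ys = ref.cell_centers()
    prepared = prep(perimeter)
    mask = np.zeros(ref.shape, dtype=bool)
    for i, y in enumerate(ys):
        for j, x in enumerate(xs):
            if prepared.contains(Point(x, y)):
                mask[i, j] = True
    return mask


def predict_map(
    model: SpatialModel,
    rasters: dict[str, RasterGrid],
    perimeter,
    floor_at_zero: bool = False,
) -> RasterGrid:
    """Linear prediction per in-perimeter pixel; nodata elsewhere.

    Negative predictions are retained by default but counted and logged; an
    optional flag floors them at zero.
    """
    for p in model.predictors:
        if p not in rasters:
            raise ValidationError(f"model predictor {p!r} has no raster")
    ref = _check_alignment(rasters) if rasters else None
    if ref is None:
        raise ValidationError("at least one predictor raster is required")
    mask = perimeter_mask(ref, perimeter)
    if not mask.any():
        warnings.warn("perimeter mask excludes every pixel; all-nodata map", stacklevel=2)
    pred = np.full(ref.shape, model.coef["const"], dtype=float)
    for p in model.predictors:
        pred = pred + model.coef[p] * rasters[p].values
    valid = mask & ~np.isnan(pred)
    n_neg = int((pred[valid] < 0).sum())
    if n_neg:
        log.info("%d in-perimeter pixel(s) predicted negative combustion", n_neg)
    if floor_at_zero:
        pred = np.maximum(pred, 0.0)
    pred = np.where(valid, pred, np.nan)
    return RasterGrid(pred, ref.x_origin, ref.y_origin, ref.pixel_size, ref.crs,
                      band="combustion", nodata=ref.nodata)


def mc_spatial_uncertainty(
    plot_df: pd.DataFrame,
    pool_sds: pd.DataFrame,
    model: SpatialModel,
    rasters: dict[str, RasterGrid],
    perimeter,
    n_sims: int = 1000,
    seed: int = 0,
    reselect: bool = False,
    predictor_sets: dict[str, list[str]] | None = None,
) -> RasterGrid:
    """Per-pixel SD of predicted combustion over a Monte Carlo ensemble.

    Per simulation, each plot's per-pool combustion (columns comb_trees,
    comb_debris, cb in ``plot_df``) is shifted by z times its plot-level SD
    (columns sd_trees, sd_debris, sd_belowground in ``pool_sds``), the model
    is refitted — same predictor labels by default, full re-selection when
    ``reselect`` — and a residual-error draw is added per pixel.
    """
    if len(plot_df) == 0:
        raise ValidationError("no plots supplied")
    ref = _check_alignment({p: rasters[p] for p in model.predictors} or rasters)
    mask = perimeter_mask(ref, perimeter)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    X = np.column_stack(
        [np.ones(len(plot_df))]
        + [plot_df[p].to_numpy(dtype=float) for p in model.predictors]
    )
    pools = ("trees", "debris", "belowground")
    base = {
        "trees": plot_df["comb_trees"].to_numpy(dtype=float),
        "debris": plot_df["comb_debris"].to_numpy(dtype=float),
        "belowground": plot_df["cb"].to_numpy(dtype=float),
    }
    sds = {p: pool_sds[f"sd_{p}"].to_numpy(dtype=float) for p in pools}

    stack = np.stack([rasters[p].values for p in model.predictors]) if model.predictors else None
    acc = np.zeros(ref.shape)
    acc2 = np.zeros(ref.shape)
    for _ in range(n_sims):
        ct = sum(base[p] + rng.standard_normal(len(plot_df)) * sds[p] for p in pools)
        if reselect and predictor_sets is not None:
            sim_df = plot_df.copy()
            sim_df["_ct"] = ct
            sim_model = select_model(sim_df, "_ct", predictor_sets)
            pred = np.full(ref.shape, sim_model.coef["const"])
            for p in sim_model.predictors:
                pred = pred + sim_model.coef[p] * rasters[p].values
            resid_sd = sim_model.resid_sd
        else:
            beta, *_ = np.linalg.lstsq(X, ct, rcond=None)
            resid = ct - X @ beta
            dof = max(len(ct) - X.shape[1], 1)
            resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
            pred = np.full(ref.shape, beta[0])
            if stack is not None:
                pred = pred + np.tensordot(beta[1:], stack, axes=1)
        pred = pred + rng.standard_normal(ref.shape) * resid_sd
        acc += pred
        acc2 += pred**2
    var = acc2 / n_sims - (acc / n_sims) ** 2
    sd = np.sqrt(np.maximum(var, 0.0)) * np.sqrt(n_sims / max(n_sims - 1, 1))
    sd = np.where(mask, sd, np.nan)
    return RasterGrid(sd, ref.x_origin, ref.y_origin, ref.pixel_size, ref.crs,
                      band="combustion_sd", nodata=ref.nodata)
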