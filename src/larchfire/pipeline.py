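"""Plot-level combustion pipeline with a precompiled fast path.

``compile_campaign`` turns a campaign into per-plot numpy arrays (per-tree
component biomass under each equation-combination strategy, debris loads,
core-level soil quantities). ``run_pipeline`` then evaluates the whole
accounting chain for a given ``PipelineParams``; the Monte Carlo framework
re-runs it thousands of times with perturbed parameters, so everything after
compilation is vectorised.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import allometry as allom
from . import soil
from .debris import DebrisParams, cwd_load, fwd_load
from .defaults import CARBON_FRACTIONS, DEBRIS_CARBON_FRACTION, SCORE_MAX_FRACTIONS
from .drivers import compute_metrics
from .io import read_horizon_params
from .types import (
    COMPONENTS,
    ArhModel,
    Campaign,
    ConfigurationError,
    HorizonProfile,
    ValidationError,
)

log = logging.getLogger(__name__)


def default_profiles() -> dict[tuple[str, str], HorizonProfile]:
    from io import StringIO

    import pandas as _pd

    from .defaults import HORIZON_PARAM_ROWS
    from .io import HORIZON_PARAM_COLUMNS

    df = _pd.DataFrame(HORIZON_PARAM_ROWS, columns=HORIZON_PARAM_COLUMNS)
    buf = StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return read_horizon_params(buf)


def plot_scar_group(campaign: Campaign, plot_id: str) -> str:
    """Scar group for profile lookup: Batamay, or Yert with/without mesic."""
    plot = campaign.plots[plot_id]
    if plot.scar_id.lower().startswith("batamay"):
        return "batamay"
    has_mesic = any(
        h.horizon == "mesic" and h.depth > 0
        for c in campaign.plot_cores(plot_id)
        for h in c.horizons
    )
    return "yert_mesic" if has_mesic else "yert_no_mesic"


@dataclass
class PipelineParams:
    """Every knob the uncertainty analysis can turn, with main-approach defaults."""

    allometry_strategy: str = "mean"  # mean | min | max
    carbon_fractions: dict[str, float] = field(default_factory=lambda: dict(CARBON_FRACTIONS))
    score_shape: str = "linear"  # linear | concave | convex
    fwd_multiplier: float = 1.0
    cwd_multiplier: float = 1.0
    debris_carbon_fraction: float = DEBRIS_CARBON_FRACTION
    debris_consumption_shift: float = 0.0
    arh_slope: float | None = None  # None -> fitted (or printed default) model
    arh_intercept: float | None = None
    profile_multiplier: float = 1.0
    core_combustion_method: str = "clip_core"  # clip_core | clip_plot
    outside_tree_method: str = "average"  # average | cores_only


def score_array(shape: str = "linear") -> np.ndarray:
    """(12, 4) consumed fraction per (score, component); monotone by construction."""
    ramp = np.arange(12) / 11.0
    if shape == "concave":
        ramp = ramp**0.7
    elif shape == "convex":
        ramp = ramp**1.5
    elif shape != "linear":
        raise ConfigurationError(f"unknown score shape {shape!r}")
    maxima = np.array([SCORE_MAX_FRACTIONS[c] for c in COMPONENTS])
    return ramp[:, None] * maxima[None, :]


@dataclass
class CompiledPlot:
    plot_id: str
    area: float
    # trees
    biomass: dict[str, np.ndarray]  # strategy -> (n_trees, 4)
    scores: np.ndarray  # (n_trees,) int
    # debris
    fwd_base: float  # kg dry mass m^-2 at default params
    cwd_base: float
    consumption_fwd: float
    consumption_cwd: float
    # soil cores
    at_tree: np.ndarray  # bool per core
    arh_ab: np.ndarray  # cm, NaN for away cores
    resid_c: np.ndarray  # kg C m^-2 per core
    resid_sol: np.ndarray  # cm per core
    profile_factor: float  # kg C m^-2 per cm of pre-fire depth
    outside_depths: np.ndarray  # cm


@dataclass
class CompiledCampaign:
    plots: list[CompiledPlot]
    arh_model: ArhModel  # main-approach reconstruction model
    campaign: Campaign


def fit_campaign_arh_model(campaign: Campaign) -> ArhModel:
    """Fit on unburned at-tree cores; fall back to the published coefficients."""
    unburned_ids = {p.plot_id for p in campaign.unburned_plots()}
    cores = [
        c for c in campaign.cores
        if c.plot_id in unburned_ids and c.at_tree and c.sol is not None and c.arh0 is not None
    ]
    if len(cores) >= 3:
        return soil.fit_arh_model(cores)
    log.info("fewer than 3 unburned at-tree cores; using default ARH model (0.96, 3.91)")
    return ArhModel()


def compile_campaign(
    campaign: Campaign,
    registry=None,
    profiles: dict[tuple[str, str], HorizonProfile] | None = None,
    debris_params: DebrisParams | None = None,
) -> CompiledCampaign:
    if registry is None:
        registry = allom.default_registry()
    if profiles is None:
        profiles = default_profiles()
    if debris_params is None:
        debris_params = DebrisParams()

    arh_model = fit_campaign_arh_model(campaign)
    compiled: list[CompiledPlot] = []
    for plot in campaign.burned_plots():
        pid = plot.plot_id
        trees = campaign.plot_trees(pid)
        n = len(trees)
        biomass = {s: np.zeros((n, len(COMPONENTS))) for s in ("mean", "min", "max")}
        scores = np.zeros(n, dtype=int)
        for i, t in enumerate(trees):
            if t.consumption_score is None:
                raise ValidationError(f"tree in burned plot {pid} lacks a consumption score")
            scores[i] = t.consumption_score
            for j, comp in enumerate(COMPONENTS):
                eqs = allom.matching_equations(registry, t.species, comp, t.diameter_type)
                if not eqs:
                    raise ConfigurationError(
                        f"no allometric equation for ({t.species}, {comp}, {t.diameter_type})"
                    )
                preds = [eq.predict(t.diameter) for eq in eqs]
                biomass["mean"][i, j] = sum(preds) / len(preds)
                biomass["min"][i, j] = min(preds)
                biomass["max"][i, j] = max(preds)

        tally = campaign.debris.get(pid)
        if tally is None:
            fwd_base = cwd_base = 0.0
            cons_fwd = cons_cwd = 0.0
        else:
            fwd_base = fwd_load(tally, debris_params)
            cwd_base = cwd_load(tally, debris_params)
            cons_fwd = tally.consumption_fwd if tally.consumption_fwd is not None else 0.0
            cons_cwd = tally.consumption_cwd if tally.consumption_cwd is not None else 0.0

        cores = campaign.plot_cores(pid)
        if not cores:
            raise ValidationError(f"burned plot {pid} has no soil cores")
        group = plot_scar_group(campaign, pid)
        key = (plot.forest_type, group)
        if key not in profiles:
            raise ConfigurationError(f"no horizon profile for {key}")
        profile = profiles[key]
        at_tree = np.array([c.at_tree for c in cores])
        arh_ab = np.array(
            [c.arh_ab if (c.at_tree and c.arh_ab is not None) else np.nan for c in cores]
        )
        if not np.any(~np.isnan(arh_ab)):
            raise ValidationError(f"burned plot {pid} has no at-tree core with ARH measurements")
        resid_c = np.array([soil.residual_soil_carbon(c.horizons, profile) for c in cores])
        resid_sol = np.array([c.horizon_depth_total() for c in cores])

        compiled.append(
            CompiledPlot(
                plot_id=pid,
                area=plot.transect_area,
                biomass=biomass,
                scores=scores,
                fwd_base=fwd_base,
                cwd_base=cwd_base,
                consumption_fwd=cons_fwd,
                consumption_cwd=cons_cwd,
                at_tree=at_tree,
                arh_ab=arh_ab,
                resid_c=resid_c,
                resid_sol=resid_sol,
                profile_factor=profile.carbon_per_cm(),
                outside_depths=np.asarray(campaign.outside_depths.get(pid, []), dtype=float),
            )
        )
    return CompiledCampaign(plots=compiled, arh_model=arh_model, campaign=campaign)


def run_pipeline(compiled: CompiledCampaign, params: PipelineParams | None = None) -> pd.DataFrame:
    """Per-plot pools and combustion under one parameterisation.

    Returns a DataFrame with one row per burned plot: pre-fire pools, per-pool
    combustion, the six response metrics, clip counters, and burn-depth means.
    """
    if params is None:
        params = PipelineParams()
    slope = params.arh_slope if params.arh_slope is not None else compiled.arh_model.slope
    intercept = (
        params.arh_intercept if params.arh_intercept is not None else compiled.arh_model.intercept
    )
    cfrac = np.array([params.carbon_fractions[c] for c in COMPONENTS])
    sarr = score_array(params.score_shape)

    rows = []
    # first pass: core-level soil accounting, pooled for the burn-depth model
    per_plot_soil = []
    all_depths: list[np.ndarray] = []
    all_comb: list[np.ndarray] = []
    for cp in compiled.plots:
        sol_pre_attree = slope * cp.arh_ab + intercept  # NaN for away cores
        plot_mean = float(np.nanmean(sol_pre_attree))
        sol_pre = np.where(np.isnan(sol_pre_attree), plot_mean, sol_pre_attree)
        sol_pre = np.maximum(sol_pre, 0.0)
        prefire_c = sol_pre * cp.profile_factor * params.profile_multiplier
        diff = prefire_c - cp.resid_c
        clipped = diff < 0
        comb_clipped = np.maximum(diff, 0.0)
        burn_depth = np.maximum(sol_pre - cp.resid_sol, 0.0)
        per_plot_soil.append((sol_pre, prefire_c, diff, comb_clipped, clipped, burn_depth))
        all_depths.append(burn_depth)
        all_comb.append(comb_clipped)

    depth_model = None
    depths_pooled = np.concatenate(all_depths)
    comb_pooled = np.concatenate(all_comb)
    if depths_pooled.size >= 2 and np.ptp(depths_pooled) > 0:
        # closed-form OLS, avoids per-run scipy overhead
        dx = depths_pooled - depths_pooled.mean()
        dy = comb_pooled - comb_pooled.mean()
        bslope = float(dx @ dy / (dx @ dx))
        bint = float(comb_pooled.mean() - bslope * depths_pooled.mean())
        ss_res = float(np.sum((dy - bslope * dx) ** 2))
        ss_tot = float(dy @ dy)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        depth_model = soil.BurnDepthModel(bslope, bint, int(depths_pooled.size), r2)

    for cp, (sol_pre, prefire_c, diff, comb_clipped, clipped, burn_depth) in zip(
        compiled.plots, per_plot_soil
    ):
        bio = cp.biomass[params.allometry_strategy]
        carbon = bio * cfrac[None, :]  # (n_trees, 4) kg C
        tree_pool = float(carbon.sum()) / cp.area
        if len(cp.scores):
            tree_comb = float((carbon * sarr[cp.scores - 1, :]).sum()) / cp.area
        else:
            tree_comb = 0.0

        fwd_pool = cp.fwd_base * params.fwd_multiplier * params.debris_carbon_fraction
        cwd_pool = cp.cwd_base * params.cwd_multiplier * params.debris_carbon_fraction
        cons_fwd = float(np.clip(cp.consumption_fwd + params.debris_consumption_shift, 0.0, 1.0))
        cons_cwd = float(np.clip(cp.consumption_cwd + params.debris_consumption_shift, 0.0, 1.0))
        fwd_comb = fwd_pool * cons_fwd
        cwd_comb = cwd_pool * cons_cwd

        if params.core_combustion_method == "clip_core":
            core_mean = float(comb_clipped.mean())
        elif params.core_combustion_method == "clip_plot":
            core_mean = max(float(diff.mean()), 0.0)
        else:
            raise ConfigurationError(
                f"unknown core combustion method {params.core_combustion_method!r}"
            )
        if params.outside_tree_method == "average" and cp.outside_depths.size and depth_model:
            below = soil.plot_belowground_combustion(
                [core_mean], list(cp.outside_depths), depth_model
            )
        elif params.outside_tree_method in ("average", "cores_only"):
            below = core_mean
        else:
            raise ConfigurationError(
                f"unknown outside-tree method {params.outside_tree_method!r}"
            )
        # the same physical-impossibility rule as at core level: plot-level
        # belowground combustion lies within [0, pre-fire pool]
        below = float(np.clip(below, 0.0, float(prefire_c.mean())))
        below_pool = float(prefire_c.mean())

        metrics = compute_metrics(
            cp.plot_id, tree_comb, fwd_comb, cwd_comb, below,
            prefire_above=tree_pool + fwd_pool + cwd_pool, prefire_below=below_pool,
        )
        rows.append(
            {
                "plot_id": cp.plot_id,
                "prefire_trees": tree_pool,
                "prefire_fwd": fwd_pool,
                "prefire_cwd": cwd_pool,
                "prefire_above": tree_pool + fwd_pool + cwd_pool,
                "prefire_below": below_pool,
                "prefire_sol": float(sol_pre.mean()),
                "comb_trees": tree_comb,
                "comb_fwd": fwd_comb,
                "comb_cwd": cwd_comb,
                "ca": metrics.ca,
                "cb": metrics.cb,
                "ct": metrics.ct,
                "pca": metrics.pca,
                "pcb": metrics.pcb,
                "pct": metrics.pct,
                "burn_depth_mean": float(burn_depth.mean()),
                "n_cores": int(len(cp.resid_c)),
                "n_clipped": int(clipped.sum()),
            }
        )

    df = pd.DataFrame(rows)
    if depth_model is not None:
        df.attrs["burn_depth_model"] = depth_model
    df.attrs["arh_model"] = compiled.arh_model
    n_clip = int(df["n_clipped"].sum()) if len(df) else 0
    if n_clip:
        log.info("negative core combustion clipped to zero at %d core(s)", n_clip)
    return df


def process_campaign(
    campaign: Campaign,
    params: PipelineParams | None = None,
    registry=None,
    profiles: dict[tuple[str, str], HorizonProfile] | None = None,
    debris_params: DebrisParams | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: compile then run with main-approach parameters."""
    compiled = compile_campaign(campaign, registry, profiles, debris_params)
    return run_pipeline(compiled, params)


def driver_table(campaign: Campaign, results: pd.DataFrame) -> pd.DataFrame:
    """Join per-plot metrics with driver covariates for model selection."""
    rows = []
    for _, r in results.iterrows():
        plot = campaign.plots[r["plot_id"]]
        w = campaign.weather.get(r["plot_id"])
        rows.append(
            {
                **r.to_dict(),
                "stand_age": plot.stand_age,
                "moisture_class": plot.moisture_class,
                "larch_proportion": plot.larch_proportion,
                "prefire_tree_biomass": r["prefire_trees"],
                "fwi": w.fwi if w else np.nan,
            }
        )
    return pd.DataFrame(rows)


def perturbed(params: PipelineParams, **changes) -> PipelineParams:
    return replace(params, **changes)
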