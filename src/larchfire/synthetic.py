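"""Synthetic field campaigns and raster stacks with a known combustion truth.

The generator emulates the statistical structure the analysis assumes: three
forest types with distinct stand density, age, and diameter distributions
(dense young larch, open mature larch, mixed larch/pine); organic soil
columns realised from the default horizon profiles; an ARH-SOL linear
relation with Gaussian noise; burn depth linked to fire weather through a
shared severity latent that also drives canopy consumption scores; and
predictor rasters with a configured linear link to true pixel combustion.

Every quantity the pipeline is supposed to estimate is recorded in a
``TruthLedger`` whose per-core bookkeeping satisfies conservation exactly
(pre-fire = residual + combusted, no clipping in truth).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from . import allometry as allom
from .debris import DebrisParams, cwd_load, fwd_load
from .defaults import CARBON_FRACTIONS
from .pipeline import default_profiles
from .rasters import RasterGrid
from .types import (
    COMPONENTS,
    Campaign,
    DebrisTally,
    FireWeatherRecord,
    HorizonProfile,
    MeasuredHorizon,
    Plot,
    SoilCore,
    TreeRecord,
)


class GenerationError(ValueError):
    """The requested configuration cannot produce a consistent campaign."""


# horizon order from the surface downwards, as fire consumes them
HORIZON_ORDER = ("live_moss", "litter", "dead_moss", "fibric", "mesic")


@dataclass
class CampaignConfig:
    """Study-condition defaults for the synthetic campaign.

    Type-level parameters follow the study design: 17/20/4 burned plots and
    6/3/3 controls across dense (young, ~24,700 stems/ha, 55 y), open
    (mature, ~10,900 stems/ha, 112 y), and mixed (131 y) stands; mean burn
    depths 8.0/10.0/10.9 cm; ARH relation SOL = 0.96 ARH_ab + 3.91 with
    ~1 cm residual scatter. Diameter medians are set so pre-fire pools land
    near 3.1 (aboveground) and 3.5 (belowground) kg C m^-2.
    """

    n_burned: dict[str, int] = field(
        default_factory=lambda: {"larch_dense": 17, "larch_open": 20, "mixed": 4}
    )
    n_unburned: dict[str, int] = field(
        default_factory=lambda: {"larch_dense": 6, "larch_open": 3, "mixed": 3}
    )
    # stems per hectare; transect tallies every stem (saplings included)
    density_stems_ha: dict[str, float] = field(
        default_factory=lambda: {"larch_dense": 24700.0, "larch_open": 10900.0, "mixed": 9000.0}
    )
    stand_age_mean: dict[str, float] = field(
        default_factory=lambda: {"larch_dense": 55.0, "larch_open": 112.0, "mixed": 131.0}
    )
    stand_age_sd: float = 8.0
    larch_proportion: dict[str, float] = field(
        default_factory=lambda: {"larch_dense": 0.80, "larch_open": 0.75, "mixed": 0.30}
    )
    # log-normal diameter distributions (median cm, sigma of log)
    dbh_median: dict[str, float] = field(
        default_factory=lambda: {"larch_dense": 3.0, "larch_open": 4.6, "mixed": 5.2}
    )
    dbh_sigma: dict[str, float] = field(
        default_factory=lambda: {"larch_dense": 0.45, "larch_open": 0.50, "mixed": 0.50}
    )
    # pre-fire soil organic layer depth per type (cm)
    sol_prefire_mean: dict[str, float] = field(
        default_factory=lambda: {"larch_dense": 13.0, "larch_open": 13.5, "mixed": 12.5}
    )
    sol_prefire_sd: float = 2.0
    # ARH-SOL relation
    arh_slope: float = 0.96
    arh_intercept: float = 3.91  # cm
    arh_resid_sd: float = 1.0  # cm
    # burn depth: type baseline + FWI sensitivity + core noise (cm)
    burn_depth_base: dict[str, float] = field(
        default_factory=lambda: {"larch_dense": 8.0, "larch_open": 10.0, "mixed": 10.9}
    )
    fwi_mean: float = 25.0
    fwi_sd: float = 6.0
    burn_depth_fwi_sens: float = 0.12  # cm per FWI unit
    burn_depth_sd: float = 1.0  # core-to-core noise
    # severity latent shared by burn depth and canopy consumption
    severity_fwi_weight: float = 0.6
    # measurement noise on horizon bulk density / C concentration (relative)
    measurement_noise: float = 0.05
    # debris tally intensity (expected FWD counts per class, CWD pieces)
    fwd_count_means: dict[str, float] = field(
        default_factory=lambda: {"fwd_0_0.5": 40.0, "fwd_0.5_1": 25.0, "fwd_1_3": 18.0, "fwd_3_7": 6.0}
    )
    cwd_piece_mean: float = 2.0
    n_outside_trees: int = 10
    cores_per_plot: int = 5
    transect_area: float = 60.0


@dataclass
class TruthLedger:
    """Ground truth recorded during generation (the acceptance surface)."""

    plots: dict[str, dict[str, float]] = field(default_factory=dict)
    cores: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def check_conservation(self, tol: float = 1e-9) -> bool:
        return all(
            abs(c["prefire_c"] - c["resid_c"] - c["comb_c"]) <= tol
            for c in self.cores.values()
        )


def _profile_for(
    profiles: dict[tuple[str, str], HorizonProfile], ftype: str, scar: str, want_mesic: bool
) -> tuple[str, HorizonProfile]:
    if scar == "Batamay":
        key = (ftype, "batamay")
    else:
        key = (ftype, "yert_mesic" if want_mesic else "yert_no_mesic")
    if key not in profiles:
        key = (ftype, "yert_no_mesic")
    return key[1], profiles[key]


def _realize_stack(
    sol: float, profile: HorizonProfile, rng: np.random.Generator, noise: float
) -> list[MeasuredHorizon]:
    """Full (pre-fire) horizon stack for a core of total depth ``sol``."""
    stack = []
    for hz in HORIZON_ORDER:
        frac = profile.frac_depth.get(hz, 0.0)
        if frac <= 0:
            continue
        rho = profile.bulk_density[hz] * max(1.0 + noise * rng.standard_normal(), 0.2)
        conc = profile.c_concentration[hz] * max(1.0 + noise * rng.standard_normal(), 0.2)
        stack.append(MeasuredHorizon(hz, depth=frac * sol, bulk_density=rho, c_concentration=conc))
    return stack


def _truncate_stack(stack: list[MeasuredHorizon], burn_depth: float) -> list[MeasuredHorizon]:
    """Remove ``burn_depth`` cm from the top of the stack."""
    remaining = []
    to_burn = burn_depth
    for hz in stack:
        if to_burn >= hz.depth:
            to_burn -= hz.depth
            continue
        remaining.append(
            MeasuredHorizon(hz.horizon, hz.depth - to_burn, hz.bulk_density, hz.c_concentration)
        )
        to_burn = 0.0
    return remaining


def _stack_carbon(stack: list[MeasuredHorizon]) -> float:
    return sum(h.depth * h.bulk_density * h.c_concentration / 100.0 for h in stack)


def _tree_truth(
    trees: list[TreeRecord], registry, score_arr: dict[int, dict[str, float]], area: float
) -> tuple[float, float]:
    pool = comb = 0.0
    for t in trees:
        bm = allom.apply_allometry(t, registry)
        carbon = {c: getattr(bm, c) * CARBON_FRACTIONS[c] for c in COMPONENTS}
        pool += sum(carbon.values())
        if t.consumption_score is not None:
            fr = score_arr[t.consumption_score]
            comb += sum(carbon[c] * fr[c] for c in COMPONENTS)
    return comb / area, pool / area


def _draw_trees(
    rng: np.random.Generator,
    plot_id: str,
    ftype: str,
    cfg: CampaignConfig,
    severity: float | None,
) -> list[TreeRecord]:
    n = int(rng.poisson(cfg.density_stems_ha[ftype] * cfg.transect_area / 1e4))
    n = max(n, 3)
    larch_p = cfg.larch_proportion[ftype]
    trees = []
    for _ in range(n):
        u = rng.random()
        if u < larch_p:
            species, dtype = "L.cajanderi", "DBH"
        elif ftype == "mixed" and u < larch_p + 0.55:
            species, dtype = "P.sylvestris", "DBH"
        elif u < larch_p + (0.55 if ftype == "mixed" else 0.08):
            species, dtype = "B.pendula", "DBH"
        else:
            species, dtype = ("Alnus", "D0") if rng.random() < 0.5 else ("Salix", "D0")
        d = float(rng.lognormal(np.log(cfg.dbh_median[ftype]), cfg.dbh_sigma[ftype]))
        d = max(min(d, 40.0), 0.3)
        if dtype == "D0":
            d = min(d, 8.0)
        score = None
        if severity is not None:
            latent = severity + 0.8 * rng.standard_normal()
            score = int(np.clip(round(7 + 2.2 * latent), 1, 12))
        trees.append(TreeRecord(plot_id, species, d, dtype, score))
    return trees


def _draw_debris(
    rng: np.random.Generator, plot_id: str, cfg: CampaignConfig, severity: float | None
) -> DebrisTally:
    counts = {cls: int(rng.poisson(mu)) for cls, mu in cfg.fwd_count_means.items()}
    n_cwd = int(rng.poisson(cfg.cwd_piece_mean))
    decays = ("sound", "intermediate", "rotten")
    pieces = [
        (float(rng.uniform(7.5, 22.0)), decays[int(rng.integers(3))]) for _ in range(n_cwd)
    ]
    cons_fwd = cons_cwd = None
    if severity is not None:
        cons_fwd = float(np.clip(0.55 + 0.12 * severity + 0.05 * rng.standard_normal(), 0.0, 1.0))
        cons_cwd = float(np.clip(0.35 + 0.12 * severity + 0.05 * rng.standard_normal(), 0.0, 1.0))
    return DebrisTally(plot_id, 30.0, counts, pieces, cons_fwd, cons_cwd)


def generate_campaign(
    config: CampaignConfig | None = None, seed: int = 0
) -> tuple[Campaign, TruthLedger]:
    """Full synthetic campaign (tables) plus its truth ledger; deterministic per seed."""
    cfg = config or CampaignConfig()
    for ftype, base in cfg.burn_depth_base.items():
        if base >= cfg.sol_prefire_mean[ftype]:
            raise GenerationError(
                f"burn depth baseline {base} cm >= pre-fire SOL mean for {ftype}; infeasible"
            )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    profiles = default_profiles()
    registry = allom.default_registry()
    from .defaults import default_score_table

    score_table = default_score_table()

    plots: dict[str, Plot] = {}
    trees: list[TreeRecord] = []
    debris: dict[str, DebrisTally] = {}
    cores: list[SoilCore] = []
    weather: dict[str, FireWeatherRecord] = {}
    outside: dict[str, list[float]] = {}
    ledger = TruthLedger()

    # grid geometry shared with generate_raster_stack: one 60x60 30 m grid per scar
    scar_origin = {"Batamay": (0.0, 0.0), "Yert": (10000.0, 0.0)}
    scar_lonlat = {"Batamay": (129.42, 63.53), "Yert": (125.79, 62.02)}
    used_cells: dict[str, set[tuple[int, int]]] = {"Batamay": set(), "Yert": set()}

    def place(scar: str) -> tuple[float, float]:
        while True:
            i, j = int(rng.integers(8, 52)), int(rng.integers(8, 52))
            if (i, j) not in used_cells[scar]:
                used_cells[scar].add((i, j))
                x0, y0 = scar_origin[scar]
                return x0 + (j + 0.5) * 30.0, y0 + 1800.0 - (i + 0.5) * 30.0

    def make_plot(idx: int, ftype: str, burned: bool) -> Plot:
        if ftype == "mixed":
            scar = "Yert"
        else:
            scar = "Batamay" if idx % 2 == 0 else "Yert"
        pid = f"{'B' if burned else 'U'}{len(plots) + 1:02d}"
        lon0, lat0 = scar_lonlat[scar]
        x, y = place(scar)
        return Plot(
            plot_id=pid,
            scar_id=scar,
            burn_status="burned" if burned else "unburned",
            forest_type=ftype,
            stand_age=float(
                max(rng.normal(cfg.stand_age_mean[ftype], cfg.stand_age_sd), 20.0)
            ),
            moisture_class=int(rng.choice([1, 2, 3], p=[0.35, 0.4, 0.25])),
            lon=lon0 + float(rng.normal(0, 0.05)),
            lat=lat0 + float(rng.normal(0, 0.03)),
            transect_area=cfg.transect_area,
            day_of_burn="2017-07-15" if burned and scar == "Batamay" else (
                "2018-07-10" if burned else None
            ),
            larch_proportion=float(
                np.clip(rng.normal(cfg.larch_proportion[ftype], 0.06), 0.05, 1.0)
            ),
            x=x,
            y=y,
        )

    debris_params = DebrisParams()

    # --- unburned control plots -------------------------------------------
    for ftype, n in cfg.n_unburned.items():
        for k in range(n):
            plot = make_plot(k, ftype, burned=False)
            plots[plot.plot_id] = plot
            trees.extend(_draw_trees(rng, plot.plot_id, ftype, cfg, severity=None))
            debris[plot.plot_id] = _draw_debris(rng, plot.plot_id, cfg, severity=None)
            want_mesic = ftype == "mixed" and rng.random() < 0.4
            _, profile = _profile_for(profiles, ftype, plot.scar_id, want_mesic)
            for c in range(cfg.cores_per_plot):
                at_tree = c not in (1, 3)
                arh_ab = float(rng.uniform(2.0, 16.0))
                sol = cfg.arh_slope * arh_ab + cfg.arh_intercept + (
                    cfg.arh_resid_sd * float(rng.standard_normal())
                )
                sol = max(sol, 2.0)
                stack = _realize_stack(sol, profile, rng, cfg.measurement_noise)
                cores.append(
                    SoilCore(
                        plot_id=plot.plot_id,
                        core_id=f"{plot.plot_id}c{c + 1}",
                        position=c * 7.5,
                        at_tree=at_tree,
                        horizons=stack,
                        sol=sol,
                        arh0=(sol - arh_ab) if at_tree else None,
                    )
                )

    # --- burned plots ------------------------------------------------------
    for ftype, n in cfg.n_burned.items():
        for k in range(n):
            plot = make_plot(k, ftype, burned=True)
            plots[plot.plot_id] = plot
            pid = plot.plot_id

            fwi = float(np.clip(rng.normal(cfg.fwi_mean, cfg.fwi_sd), 3.0, 45.0))
            severity = cfg.severity_fwi_weight * (fwi - cfg.fwi_mean) / cfg.fwi_sd + (
                0.8 * float(rng.standard_normal())
            )
            temp = float(rng.normal(25.0, 4.0))
            rh = float(np.clip(rng.normal(40.0, 10.0), 10.0, 90.0))
            weather[pid] = FireWeatherRecord(
                plot_id=pid,
                ffmc=float(np.clip(85 + 0.3 * fwi + rng.normal(0, 1.5), 60, 99)),
                dmc=max(float(2.2 * fwi + rng.normal(0, 6)), 1.0),
                dc=max(float(11 * fwi + rng.normal(0, 40)), 20.0),
                isi=max(float(0.35 * fwi + rng.normal(0, 1)), 0.2),
                bui=max(float(2.6 * fwi + rng.normal(0, 8)), 2.0),
                fwi=fwi,
                dsr=float(0.0272 * fwi**1.77),
                temp_c=temp,
                rh=rh,
            )

            plot_trees = _draw_trees(rng, pid, ftype, cfg, severity)
            trees.extend(plot_trees)
            tally = _draw_debris(rng, pid, cfg, severity)
            debris[pid] = tally

            want_mesic = ftype == "mixed" and rng.random() < 0.4
            _, profile = _profile_for(profiles, ftype, plot.scar_id, want_mesic)
            depth_plot = (
                cfg.burn_depth_base[ftype]
                + cfg.burn_depth_fwi_sens * (fwi - cfg.fwi_mean)
                + 0.5 * severity
            )
            core_truth_comb = []
            for c in range(cfg.cores_per_plot):
                at_tree = c not in (1, 3)
                sol_pre = float(
                    max(rng.normal(cfg.sol_prefire_mean[ftype], cfg.sol_prefire_sd), 4.0)
                )
                depth = float(
                    np.clip(
                        depth_plot + cfg.burn_depth_sd * rng.standard_normal(),
                        1.0,
                        sol_pre - 0.5,
                    )
                )
                full_stack = _realize_stack(sol_pre, profile, rng, cfg.measurement_noise)
                resid_stack = _truncate_stack(full_stack, depth)
                prefire_c = _stack_carbon(full_stack)
                resid_c = _stack_carbon(resid_stack)
                resid_sol = sum(h.depth for h in resid_stack)
                arh_ab = (
                    sol_pre
                    - cfg.arh_intercept
                    - cfg.arh_resid_sd * float(rng.standard_normal())
                ) / cfg.arh_slope
                core = SoilCore(
                    plot_id=pid,
                    core_id=f"{pid}c{c + 1}",
                    position=c * 7.5,
                    at_tree=at_tree,
                    horizons=resid_stack,
                    sol=resid_sol,
                    arh0=(resid_sol - arh_ab) if at_tree else None,
                )
                cores.append(core)
                ledger.cores[(pid, core.core_id)] = {
                    "sol_prefire": sol_pre,
                    "burn_depth": depth,
                    "prefire_c": prefire_c,
                    "resid_c": resid_c,
                    "comb_c": prefire_c - resid_c,
                }
                core_truth_comb.append(prefire_c - resid_c)

            if cfg.n_outside_trees:
                outside[pid] = [
                    float(np.clip(depth_plot + cfg.burn_depth_sd * rng.standard_normal(), 1.0, 20.0))
                    for _ in range(cfg.n_outside_trees)
                ]

            t_comb, t_pool = _tree_truth(plot_trees, registry, score_table, cfg.transect_area)
            fwd_pool = fwd_load(tally, debris_params) * debris_params.carbon_fraction
            cwd_pool = cwd_load(tally, debris_params) * debris_params.carbon_fraction
            ledger.plots[pid] = {
                "severity": severity,
                "prefire_trees": t_pool,
                "prefire_fwd": fwd_pool,
                "prefire_cwd": cwd_pool,
                "prefire_below": float(
                    np.mean([ledger.cores[(pid, f"{pid}c{c + 1}")]["prefire_c"]
                             for c in range(cfg.cores_per_plot)])
                ),
                "comb_trees": t_comb,
                "comb_fwd": fwd_pool * (tally.consumption_fwd or 0.0),
                "comb_cwd": cwd_pool * (tally.consumption_cwd or 0.0),
                "comb_below": float(np.mean(core_truth_comb)),
            }

    campaign = Campaign(
        plots=plots, trees=trees, debris=debris, cores=cores, weather=weather,
        outside_depths=outside,
    )
    return campaign, ledger


@dataclass
class RasterStack:
    rasters: dict[str, RasterGrid]  # slope, dnbr, sand
    perimeter: Polygon
    truth: RasterGrid  # true pixel combustion, kg C m^-2


def _smooth_field(rng: np.random.Generator, n: int, scale: float, base: float, amp: float) -> np.ndarray:
    """Low-frequency random field: sum of a few random plane waves."""
    xs = np.arange(n) / n
    X, Y = np.meshgrid(xs, xs)
    f = np.zeros((n, n))
    for _ in range(6):
        kx, ky = rng.uniform(-3, 3, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        f += rng.normal(0, 1) * np.sin(2 * np.pi * (kx * X + ky * Y) + phase)
    f = f / np.std(f)
    return base + amp * f * scale


DEFAULT_LINK = {"const": 1.0, "slope": -0.08, "dnbr": 0.006, "sand": -0.01}


def generate_raster_stack(
    config: CampaignConfig | None = None,
    campaign: Campaign | None = None,
    seed: int = 0,
    ledger: TruthLedger | None = None,
    link: dict[str, float] | None = None,
    link_noise_sd: float = 0.15,
    n: int = 60,
    crs: str = "SYNTHETIC-UTM-52N",
) -> dict[str, RasterStack]:
    """Predictor rasters, perimeter, and pixel-combustion truth per fire scar.

    When a campaign (and optionally its ledger) is given, the dNBR field is
    locally adjusted so its value at each plot tracks the plot's severity,
    coupling the field data to the raster world; plots must fall inside the
    scar perimeter.
    """
    cfg = config or CampaignConfig()
    link = dict(DEFAULT_LINK if link is None else link)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    scar_origin = {"Batamay": (0.0, 0.0), "Yert": (10000.0, 0.0)}
    out: dict[str, RasterStack] = {}
    for scar, (x0, y0) in scar_origin.items():
        slope = np.clip(_smooth_field(rng, n, 1.0, 2.4, 1.8), 0.0, None)
        dnbr = _smooth_field(rng, n, 1.0, 320.0, 90.0)
        sand = np.clip(_smooth_field(rng, n, 1.0, 45.0, 12.0), 0.0, 100.0)
        top = y0 + n * 30.0

        if campaign is not None:
            for plot in campaign.burned_plots():
                if plot.scar_id != scar:
                    continue
                j = int((plot.x - x0) / 30.0)
                i = int((top - plot.y) / 30.0)
                if not (0 <= i < n and 0 <= j < n):
                    raise GenerationError(f"plot {plot.plot_id} lies outside the {scar} grid")
                if ledger is not None:
                    target = 320.0 + 110.0 * ledger.plots[plot.plot_id]["severity"]
                    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
                    bump = np.exp(-((ii - i) ** 2 + (jj - j) ** 2) / (2 * 2.0**2))
                    dnbr = dnbr + (target - dnbr[i, j]) * bump

        truth_vals = (
            link["const"]
            + link["slope"] * slope
            + link["dnbr"] * dnbr
            + link["sand"] * sand
        )
        if link_noise_sd > 0:
            truth_vals = truth_vals + link_noise_sd * rng.standard_normal((n, n))

        def grid(vals: np.ndarray, band: str) -> RasterGrid:
            return RasterGrid(vals, x_origin=x0, y_origin=top, pixel_size=30.0, crs=crs, band=band)

        # irregular convex-ish perimeter inset from the grid edge
        margin = 2 * 30.0
        jitter = rng.uniform(0, 60.0, size=4)
        perimeter = Polygon(
            [
                (x0 + margin + jitter[0], y0 + margin),
                (x0 + n * 30.0 - margin, y0 + margin + jitter[1]),
                (x0 + n * 30.0 - margin - jitter[2], y0 + n * 30.0 - margin),
                (x0 + margin, y0 + n * 30.0 - margin - jitter[3]),
            ]
        )
        if campaign is not None:
            from shapely.geometry import Point

            for plot in campaign.burned_plots():
                if plot.scar_id == scar and not perimeter.contains(Point(plot.x, plot.y)):
                    raise GenerationError(
                        f"plot {plot.plot_id} falls outside the {scar} perimeter"
                    )
        out[scar] = RasterStack(
            rasters={"slope": grid(slope, "slope"), "dnbr": grid(dnbr, "dnbr"),
                     "sand": grid(sand, "sand")},
            perimeter=perimeter,
            truth=grid(truth_vals, "combustion_truth"),
        )
    return out


def generate_arh_cores(
    n: int = 148,
    slope: float = 0.96,
    intercept: float = 3.91,
    resid_sd: float = 1.0,
    seed: int = 0,
    arh_range: tuple[float, float] = (1.0, 17.0),
) -> list[SoilCore]:
    """Unburned at-tree cores drawn from the configured ARH-SOL relation.

    Convenience generator for reconstruction-model recovery experiments; the
    default root-height range spans the organic depths seen in the field
    (roughly 5-20 cm of soil organic layer).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cores = []
    for i in range(n):
        arh_ab = float(rng.uniform(*arh_range))
        sol = slope * arh_ab + intercept + resid_sd * float(rng.standard_normal())
        cores.append(
            SoilCore(
                plot_id="U00",
                core_id=f"arh{i}",
                position=0.0,
                at_tree=True,
                sol=max(sol, 0.5),
                arh0=max(sol, 0.5) - arh_ab,
            )
        )
    return cores
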