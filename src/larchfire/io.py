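"""Delimited-text campaign I/O with schema validation.

One CSV per entity: plots, trees, debris, cores, outside_depths, weather,
plus a horizon-parameter table. Long formats with documented headers; units
are fixed at this boundary (cm, g cm^-3, g C kg^-1, m). Every reader/writer
pair round-trips, and no row is dropped silently: recoverable issues land in
the validation report, contract violations raise.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path

import pandas as pd

from .types import (
    Campaign,
    DebrisTally,
    FireWeatherRecord,
    HorizonProfile,
    MeasuredHorizon,
    Plot,
    ReferenceError_,
    SchemaError,
    SoilCore,
    TreeRecord,
    ValidationError,
)

log = logging.getLogger(__name__)

PLOT_COLUMNS = [
    "plot_id", "scar_id", "burn_status", "forest_type", "stand_age", "moisture_class",
    "lon", "lat", "transect_area", "day_of_burn", "larch_proportion", "x", "y",
]
TREE_COLUMNS = ["plot_id", "species", "diameter_cm", "diameter_type", "consumption_score"]
DEBRIS_COLUMNS = [
    "plot_id", "kind", "class_label", "count", "diameter_cm", "decay_class",
    "line_length_m", "consumption_fwd", "consumption_cwd",
]
CORE_COLUMNS = [
    "plot_id", "core_id", "position_m", "at_tree", "sol_cm", "arh0_cm",
    "horizon", "depth_cm", "bulk_density", "c_concentration",
]
OUTSIDE_COLUMNS = ["plot_id", "burn_depth_cm"]
WEATHER_COLUMNS = ["plot_id", "ffmc", "dmc", "dc", "isi", "bui", "fwi", "dsr", "temp_c", "rh"]
HORIZON_PARAM_COLUMNS = [
    "forest_type", "scar_group", "horizon", "frac_depth", "bulk_density", "c_concentration",
]


def _require(df: pd.DataFrame, columns: list[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r} missing required column(s): {', '.join(missing)}")


def _opt(value):
    """None for blank/NaN cells."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return value


def read_horizon_params(path: str | Path) -> dict[tuple[str, str], HorizonProfile]:
    """Horizon parameter table keyed by (forest_type, scar_group)."""
    df = pd.read_csv(path)
    _require(df, HORIZON_PARAM_COLUMNS, "horizon_params")
    profiles: dict[tuple[str, str], HorizonProfile] = {}
    for (ftype, group), sub in df.groupby(["forest_type", "scar_group"]):
        for _, row in sub.iterrows():
            if row["bulk_density"] <= 0 or row["c_concentration"] <= 0:
                raise ValidationError(
                    f"non-positive density/concentration for ({ftype}, {group}, {row['horizon']})"
                )
        profiles[(ftype, group)] = HorizonProfile(
            forest_type=ftype,
            scar_group=group,
            frac_depth=dict(zip(sub["horizon"], sub["frac_depth"])),
            bulk_density=dict(zip(sub["horizon"], sub["bulk_density"])),
            c_concentration=dict(zip(sub["horizon"], sub["c_concentration"])),
        )
    return profiles


def write_horizon_params(profiles: dict[tuple[str, str], HorizonProfile], path: str | Path) -> None:
    rows = []
    for (ftype, group), prof in profiles.items():
        for hz, frac in prof.frac_depth.items():
            rows.append(
                {
                    "forest_type": ftype, "scar_group": group, "horizon": hz,
                    "frac_depth": frac, "bulk_density": prof.bulk_density[hz],
                    "c_concentration": prof.c_concentration[hz],
                }
            )
    pd.DataFrame(rows, columns=HORIZON_PARAM_COLUMNS).to_csv(path, index=False)


def read_campaign(directory: str | Path) -> tuple[Campaign, list[dict]]:
    """Read a full campaign table set from a directory.

    Returns the cross-referenced campaign plus a validation report (one entry
    per flagged row, with a reason code). Schema, reference, and enumeration
    violations raise.
    """
    directory = Path(directory)
    report: list[dict] = []

    plots_df = pd.read_csv(directory / "plots.csv")
    _require(plots_df, PLOT_COLUMNS, "plots")
    plots: dict[str, Plot] = {}
    for _, row in plots_df.iterrows():
        plot = Plot(
            plot_id=str(row["plot_id"]),
            scar_id=str(row["scar_id"]),
            burn_status=row["burn_status"],
            forest_type=row["forest_type"],
            stand_age=float(row["stand_age"]),
            moisture_class=int(row["moisture_class"]),
            lon=float(row["lon"]),
            lat=float(row["lat"]),
            transect_area=float(row["transect_area"]),
            day_of_burn=_opt(row["day_of_burn"]),
            larch_proportion=_opt(row["larch_proportion"]),
            x=_opt(row["x"]),
            y=_opt(row["y"]),
        )
        plots[plot.plot_id] = plot

    def check_plot(plot_id: str, table: str) -> str:
        pid = str(plot_id)
        if pid not in plots:
            raise ReferenceError_(f"{table} row references unknown plot {pid!r}")
        return pid

    trees: list[TreeRecord] = []
    trees_path = directory / "trees.csv"
    if trees_path.exists():
        trees_df = pd.read_csv(trees_path)
        if len(trees_df):
            _require(trees_df, TREE_COLUMNS, "trees")
        for _, row in trees_df.iterrows():
            score = _opt(row["consumption_score"])
            trees.append(
                TreeRecord(
                    plot_id=check_plot(row["plot_id"], "trees"),
                    species=row["species"],
                    diameter=float(row["diameter_cm"]),
                    diameter_type=row["diameter_type"],
                    consumption_score=None if score is None else int(score),
                )
            )

    debris: dict[str, DebrisTally] = {}
    debris_path = directory / "debris.csv"
    if debris_path.exists():
        debris_df = pd.read_csv(debris_path)
        if len(debris_df):
            _require(debris_df, DEBRIS_COLUMNS, "debris")
        for pid_raw, sub in debris_df.groupby("plot_id"):
            pid = check_plot(pid_raw, "debris")
            meta = sub[sub["kind"] == "plot"]
            if meta.empty:
                report.append({"table": "debris", "plot_id": pid, "reason": "missing plot meta row; defaults used"})
                line_length, cons_fwd, cons_cwd = 30.0, None, None
            else:
                m = meta.iloc[0]
                line_length = float(m["line_length_m"])
                cons_fwd = _opt(m["consumption_fwd"])
                cons_cwd = _opt(m["consumption_cwd"])
            fwd_counts = {
                str(r["class_label"]): int(r["count"])
                for _, r in sub[sub["kind"] == "fwd"].iterrows()
            }
            cwd_pieces = [
                (float(r["diameter_cm"]), str(r["decay_class"]))
                for _, r in sub[sub["kind"] == "cwd"].iterrows()
            ]
            debris[pid] = DebrisTally(
                plot_id=pid,
                line_length=line_length,
                fwd_counts=fwd_counts,
                cwd_pieces=cwd_pieces,
                consumption_fwd=None if cons_fwd is None else float(cons_fwd),
                consumption_cwd=None if cons_cwd is None else float(cons_cwd),
            )

    cores: list[SoilCore] = []
    cores_path = directory / "cores.csv"
    if cores_path.exists():
        cores_df = pd.read_csv(cores_path)
        if len(cores_df):
            _require(cores_df, CORE_COLUMNS, "cores")
        for (pid_raw, core_id), sub in cores_df.groupby(["plot_id", "core_id"]):
            pid = check_plot(pid_raw, "cores")
            first = sub.iloc[0]
            horizons = []
            for _, r in sub.iterrows():
                hz = _opt(r["horizon"])
                if hz is None:
                    continue  # fully combusted core: placeholder row, no horizon
                horizons.append(
                    MeasuredHorizon(
                        horizon=str(hz),
                        depth=float(r["depth_cm"]),
                        bulk_density=_opt(r["bulk_density"]),
                        c_concentration=_opt(r["c_concentration"]),
                    )
                )
            core = SoilCore(
                plot_id=pid,
                core_id=str(core_id),
                position=float(first["position_m"]),
                at_tree=bool(first["at_tree"]),
                horizons=horizons,
                sol=_opt(first["sol_cm"]),
                arh0=_opt(first["arh0_cm"]),
            )
            if core.sol is not None and abs(core.horizon_depth_total() - core.sol) > 0.1:
                report.append(
                    {"table": "cores", "plot_id": pid, "core_id": core.core_id,
                     "reason": f"horizon depths sum to {core.horizon_depth_total():.2f} cm, SOL={core.sol:.2f} cm"}
                )
            if plots[pid].burn_status == "burned" and any(
                h.horizon == "live_moss" and h.depth > 0 for h in horizons
            ):
                report.append(
                    {"table": "cores", "plot_id": pid, "core_id": core.core_id,
                     "reason": "live moss in a burned core: possible post-fire accumulation"}
                )
            cores.append(core)

    outside: dict[str, list[float]] = {}
    outside_path = directory / "outside_depths.csv"
    if outside_path.exists():
        out_df = pd.read_csv(outside_path)
        if len(out_df):
            _require(out_df, OUTSIDE_COLUMNS, "outside_depths")
        for _, row in out_df.iterrows():
            pid = check_plot(row["plot_id"], "outside_depths")
            outside.setdefault(pid, []).append(float(row["burn_depth_cm"]))

    weather: dict[str, FireWeatherRecord] = {}
    weather_path = directory / "weather.csv"
    if weather_path.exists():
        wdf = pd.read_csv(weather_path)
        if len(wdf):
            _require(wdf, WEATHER_COLUMNS, "weather")
        for _, row in wdf.iterrows():
            pid = check_plot(row["plot_id"], "weather")
            weather[pid] = FireWeatherRecord(
                plot_id=pid,
                ffmc=float(row["ffmc"]), dmc=float(row["dmc"]), dc=float(row["dc"]),
                isi=float(row["isi"]), bui=float(row["bui"]), fwi=float(row["fwi"]),
                dsr=float(row["dsr"]), temp_c=float(row["temp_c"]), rh=float(row["rh"]),
            )

    campaign = Campaign(
        plots=plots, trees=trees, debris=debris, cores=cores, weather=weather,
        outside_depths=outside,
    )
    log.info(
        "read campaign: %d plots, %d trees, %d debris tallies, %d cores, %d weather records, %d flagged rows",
        len(plots), len(trees), len(debris), len(cores), len(weather), len(report),
    )
    return campaign, report


def write_campaign(campaign: Campaign, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "plot_id": p.plot_id, "scar_id": p.scar_id, "burn_status": p.burn_status,
                "forest_type": p.forest_type, "stand_age": p.stand_age,
                "moisture_class": p.moisture_class, "lon": p.lon, "lat": p.lat,
                "transect_area": p.transect_area, "day_of_burn": p.day_of_burn,
                "larch_proportion": p.larch_proportion, "x": p.x, "y": p.y,
            }
            for p in campaign.plots.values()
        ],
        columns=PLOT_COLUMNS,
    ).to_csv(directory / "plots.csv", index=False)

    pd.DataFrame(
        [
            {
                "plot_id": t.plot_id, "species": t.species, "diameter_cm": t.diameter,
                "diameter_type": t.diameter_type, "consumption_score": t.consumption_score,
            }
            for t in campaign.trees
        ],
        columns=TREE_COLUMNS,
    ).to_csv(directory / "trees.csv", index=False)

    debris_rows = []
    for tally in campaign.debris.values():
        debris_rows.append(
            {"plot_id": tally.plot_id, "kind": "plot", "line_length_m": tally.line_length,
             "consumption_fwd": tally.consumption_fwd, "consumption_cwd": tally.consumption_cwd}
        )
        for cls, n in tally.fwd_counts.items():
            debris_rows.append({"plot_id": tally.plot_id, "kind": "fwd", "class_label": cls, "count": n})
        for d, decay in tally.cwd_pieces:
            debris_rows.append(
                {"plot_id": tally.plot_id, "kind": "cwd", "diameter_cm": d, "decay_class": decay}
            )
    pd.DataFrame(debris_rows, columns=DEBRIS_COLUMNS).to_csv(directory / "debris.csv", index=False)

    core_rows = []
    for core in campaign.cores:
        base = {
            "plot_id": core.plot_id, "core_id": core.core_id, "position_m": core.position,
            "at_tree": core.at_tree, "sol_cm": core.sol, "arh0_cm": core.arh0,
        }
        if not core.horizons:
            core_rows.append(base)
        for hz in core.horizons:
            core_rows.append(
                {**base, "horizon": hz.horizon, "depth_cm": hz.depth,
                 "bulk_density": hz.bulk_density, "c_concentration": hz.c_concentration}
            )
    pd.DataFrame(core_rows, columns=CORE_COLUMNS).to_csv(directory / "cores.csv", index=False)

    pd.DataFrame(
        [
            {"plot_id": pid, "burn_depth_cm": d}
            for pid, depths in campaign.outside_depths.items()
            for d in depths
        ],
        columns=OUTSIDE_COLUMNS,
    ).to_csv(directory / "outside_depths.csv", index=False)

    pd.DataFrame(
        [
            {
                "plot_id": w.plot_id, "ffmc": w.ffmc, "dmc": w.dmc, "dc": w.dc,
                "isi": w.isi, "bui": w.bui, "fwi": w.fwi, "dsr": w.dsr,
                "temp_c": w.temp_c, "rh": w.rh,
            }
            for w in campaign.weather.values()
        ],
        columns=WEATHER_COLUMNS,
    ).to_csv(directory / "weather.csv", index=False)
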