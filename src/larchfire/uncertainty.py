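"""Monte Carlo uncertainty quantification and source attribution.

Each named error source perturbs the pipeline parameterisation either by
drawing influential parameters from a distribution or by switching between
alternative methods. An ensemble (default 1000 runs) re-executes the full
accounting chain per draw; uncertainty is the standard deviation of the
campaign-mean combustion over runs. Source attribution re-runs the ensemble
under "source removed" (the pool's sources frozen at main-approach values)
and "source only" (every other source frozen) scenarios.

One master seed spawns an independent substream per (run, source), so the
scenario families share common random numbers: freezing one source leaves
every other source's draws bit-identical, sharpening attribution contrasts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pipeline import CompiledCampaign, PipelineParams, perturbed, run_pipeline
from .types import ConfigurationError

POOLS = ("trees", "debris", "belowground")


@dataclass
class PerturbationSpec:
    source: str
    kind: str  # parameter-normal | parameter-uniform | method-switch
    pool: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pool not in POOLS:
            raise ConfigurationError(f"unknown pool {self.pool!r}")
        if self.kind == "parameter-normal" and self.params.get("sd", 0.0) < 0:
            raise ConfigurationError("normal SD must be >= 0")
        if self.kind == "method-switch" and len(self.params.get("alternatives", [])) < 2:
            raise ConfigurationError("method-switch needs at least 2 alternatives")


def _switch(rng: np.random.Generator, alternatives: list) -> object:
    return alternatives[int(rng.integers(len(alternatives)))]


def _apply_allometry_choice(p, rng, kw):
    return perturbed(p, allometry_strategy=_switch(rng, kw["alternatives"]))


def _apply_tree_c(p, rng, kw):
    # one systematic shift applied to every component's C concentration
    shift = kw["sd"] * rng.standard_normal()
    fr = {c: max(v + shift, 0.01) for c, v in p.carbon_fractions.items()}
    return perturbed(p, carbon_fractions=fr)


def _apply_score_mapping(p, rng, kw):
    return perturbed(p, score_shape=_switch(rng, kw["alternatives"]))


def _apply_fwd_params(p, rng, kw):
    return perturbed(p, fwd_multiplier=max(1.0 + kw["sd_rel"] * rng.standard_normal(), 0.0))


def _apply_cwd_params(p, rng, kw):
    return perturbed(p, cwd_multiplier=max(1.0 + kw["sd_rel"] * rng.standard_normal(), 0.0))


def _apply_debris_c(p, rng, kw):
    return perturbed(
        p, debris_carbon_fraction=max(p.debris_carbon_fraction + kw["sd"] * rng.standard_normal(), 0.01)
    )


def _apply_debris_consumption(p, rng, kw):
    return perturbed(p, debris_consumption_shift=kw["sd"] * rng.standard_normal())


def _apply_arh_model(p, rng, kw, base_model):
    slope = base_model.slope + kw["sd_slope"] * rng.standard_normal()
    intercept = base_model.intercept + kw["sd_intercept"] * rng.standard_normal()
    return perturbed(p, arh_slope=slope, arh_intercept=intercept)


def _apply_profile(p, rng, kw):
    return perturbed(p, profile_multiplier=max(1.0 + kw["sd_rel"] * rng.standard_normal(), 0.0))


def _apply_core_calc(p, rng, kw):
    return perturbed(p, core_combustion_method=_switch(rng, kw["alternatives"]))


def _apply_outside_calc(p, rng, kw):
    return perturbed(p, outside_tree_method=_switch(rng, kw["alternatives"]))


APPLIERS = {
    "allometry-choice": _apply_allometry_choice,
    "tree-c-percent": _apply_tree_c,
    "score-mapping": _apply_score_mapping,
    "fwd-params": _apply_fwd_params,
    "cwd-params": _apply_cwd_params,
    "debris-c-percent": _apply_debris_c,
    "debris-consumption": _apply_debris_consumption,
    "arh-model": _apply_arh_model,
    "profile-density-concentration": _apply_profile,
    "core-combustion-calc": _apply_core_calc,
    "outside-tree-calc": _apply_outside_calc,
}


def default_specs() -> list[PerturbationSpec]:
    """The default error-source registry.

    Tree carbon percentages vary normally with SD 3 percentage points around
    their literature values; the remaining SDs and method alternatives are
    editable, provisional defaults.
    """
    return [
        PerturbationSpec("allometry-choice", "method-switch", "trees",
                         {"alternatives": ["mean", "min", "max"]}),
        PerturbationSpec("tree-c-percent", "parameter-normal", "trees", {"sd": 0.03}),
        PerturbationSpec("score-mapping", "method-switch", "trees",
                         {"alternatives": ["linear", "concave", "convex"]}),
        PerturbationSpec("fwd-params", "parameter-normal", "debris", {"sd_rel": 0.10}),
        PerturbationSpec("cwd-params", "parameter-normal", "debris", {"sd_rel": 0.10}),
        PerturbationSpec("debris-c-percent", "parameter-normal", "debris", {"sd": 0.03}),
        PerturbationSpec("debris-consumption", "parameter-normal", "debris", {"sd": 0.10}),
        PerturbationSpec("arh-model", "parameter-normal", "belowground",
                         {"sd_slope": 0.04, "sd_intercept": 0.40}),
        PerturbationSpec("profile-density-concentration", "parameter-normal", "belowground",
                         {"sd_rel": 0.15}),
        PerturbationSpec("core-combustion-calc", "method-switch", "belowground",
                         {"alternatives": ["clip_core", "clip_plot"]}),
        PerturbationSpec("outside-tree-calc", "method-switch", "belowground",
                         {"alternatives": ["average", "cores_only"]}),
    ]


@dataclass
class McResult:
    scenario: str
    n_sims: int
    seed: int
    mean_draws: pd.DataFrame  # one row per run: campaign means of ca, cb, ct
    plot_ct: np.ndarray  # (n_sims, n_plots)
    plot_ids: list[str]

    @property
    def summary(self) -> dict[str, dict[str, float]]:
        return {
            m: {"mean": float(self.mean_draws[m].mean()), "sd": float(self.mean_draws[m].std(ddof=1))}
            for m in ("ca", "cb", "ct")
        }


def _scenario_label(scenario) -> str:
    if scenario == "all":
        return "all"
    kind, pool = scenario
    return f"{kind}({pool})"


def _frozen_sources(specs: list[PerturbationSpec], scenario) -> set[str]:
    if scenario == "all":
        return set()
    kind, pool = scenario
    if kind == "source_removed":
        return {s.source for s in specs if s.pool == pool}
    if kind == "source_only":
        return {s.source for s in specs if s.pool != pool}
    raise ConfigurationError(f"unknown scenario {scenario!r}")


def run_mc(
    compiled: CompiledCampaign,
    specs: list[PerturbationSpec] | None = None,
    scenario="all",
    n_sims: int = 1000,
    seed: int = 0,
) -> McResult:
    """Monte Carlo ensemble over the compiled campaign.

    ``scenario`` is "all", ("source_removed", pool), or ("source_only", pool).
    Deterministic given seed; the (run, source) substream layout depends only
    on the position of each source in ``specs``, never on the scenario.
    """
    if specs is None:
        specs = default_specs()
    for s in specs:
        if s.source not in APPLIERS:
            raise ConfigurationError(f"spec references unknown source {s.source!r}")
    frozen = _frozen_sources(specs, scenario)

    master = np.random.SeedSequence(seed)
    run_seqs = master.spawn(n_sims)
    means = np.zeros((n_sims, 3))
    plot_ct = None
    plot_ids: list[str] = []
    for i in range(n_sims):
        src_seqs = run_seqs[i].spawn(len(specs))
        params = PipelineParams()
        for spec, sseq in zip(specs, src_seqs):
            if spec.source in frozen:
                continue
            rng = np.random.default_rng(sseq)
            if spec.source == "arh-model":
                params = APPLIERS[spec.source](params, rng, spec.params, compiled.arh_model)
            else:
                params = APPLIERS[spec.source](params, rng, spec.params)
        df = run_pipeline(compiled, params)
        if plot_ct is None:
            plot_ids = list(df["plot_id"])
            plot_ct = np.zeros((n_sims, len(plot_ids)))
        plot_ct[i] = df["ct"].to_numpy()
        means[i] = [df["ca"].mean(), df["cb"].mean(), df["ct"].mean()]

    return McResult(
        scenario=_scenario_label(scenario),
        n_sims=n_sims,
        seed=seed,
        mean_draws=pd.DataFrame(means, columns=["ca", "cb", "ct"]),
        plot_ct=plot_ct if plot_ct is not None else np.zeros((n_sims, 0)),
        plot_ids=plot_ids,
    )


def attribute_sources(
    compiled: CompiledCampaign,
    specs: list[PerturbationSpec] | None = None,
    pools: tuple[str, ...] = POOLS,
    n_sims: int = 1000,
    seed: int = 0,
    metric: str = "ct",
) -> dict:
    """Per-pool uncertainty decomposition via removed/only scenarios.

    Returns {"all": McResult, pool: {"sd_all", "sd_removed", "sd_only",
    "removed": McResult, "only": McResult}, ...}. All scenario families share
    the same seed, hence common random numbers.
    """
    if specs is None:
        specs = default_specs()
    if not pools:
        raise ConfigurationError("need at least one pool")
    base = run_mc(compiled, specs, "all", n_sims, seed)
    sd_all = base.summary[metric]["sd"]
    out: dict = {"all": base}
    for pool in pools:
        removed = run_mc(compiled, specs, ("source_removed", pool), n_sims, seed)
        only = run_mc(compiled, specs, ("source_only", pool), n_sims, seed)
        out[pool] = {
            "sd_all": sd_all,
            "sd_removed": removed.summary[metric]["sd"],
            "sd_only": only.summary[metric]["sd"],
            "removed": removed,
            "only": only,
        }
    return out


def attribution_table(attribution: dict, metric: str = "ct") -> pd.DataFrame:
    """Tidy (scenario, pool, sd, mean) table of an attribution run."""
    rows = []
    base = attribution["all"]
    rows.append({"scenario": "all", "pool": "", "mean": base.summary[metric]["mean"],
                 "sd": base.summary[metric]["sd"]})
    for pool in POOLS:
        if pool not in attribution:
            continue
        for label in ("removed", "only"):
            res = attribution[pool][label]
            rows.append({"scenario": f"source_{label}", "pool": pool,
                         "mean": res.summary[metric]["mean"], "sd": res.summary[metric]["sd"]})
    return pd.DataFrame(rows)
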