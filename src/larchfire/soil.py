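"""Belowground combustion: pre-fire soil reconstruction and carbon accounting.

Pre-fire soil organic layer depth (SOL, cm) at burned cores next to trees is
reconstructed from the adventitious root height above mineral soil
(ARH_ab = SOL - ARH_0) via a linear relation fitted on unburned at-tree cores
(default SOL = 0.96 * ARH_ab + 3.91); away-from-tree cores take the plot mean
of at-tree reconstructions. Pre-fire soil carbon per core is the reconstructed
depth times the fractional-depth-weighted sum of horizon bulk density and
carbon concentration from unburned-plot profiles; residual carbon is the sum
of measured residual horizon stocks. Combustion is the difference, clipped at
zero (negative combustion is physically impossible); plot-level belowground
combustion averages the transect-core mean with a burn-depth-regression
estimate at ten trees outside the transect.

Unit convention: kg C m^-2 = cm x g cm^-3 x (g C kg^-1) / 100.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import ArhModel, HorizonProfile, MeasuredHorizon, SoilCore, ValidationError

log = logging.getLogger(__name__)

UNIT_FACTOR = 1.0 / 100.0  # cm * g cm^-3 * g C kg^-1 -> kg C m^-2


class DegenerateDesignError(ValueError):
    """Regression design has no variation."""


@dataclass
class BurnDepthModel:
    """Linear transfer from burn depth (cm) to soil combustion (kg C m^-2)."""

    slope: float
    intercept: float
    n: int
    r2: float

    def predict(self, depth_cm: float) -> float:
        return self.slope * depth_cm + self.intercept


def fit_arh_model(cores: list[SoilCore]) -> ArhModel:
    """OLS of SOL on ARH_ab over unburned at-tree cores."""
    pairs = [(c.arh_ab, c.sol) for c in cores if c.at_tree and c.arh_ab is not None and c.sol is not None]
    if len(pairs) < 2:
        raise ValidationError("need at least two at-tree cores with SOL and ARH_0")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all ARH_ab values identical")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = max(len(x) - 2, 1)
    return ArhModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(x),
        r2=float(res.rvalue**2),
        resid_sd=float(np.sqrt(np.sum(resid**2) / dof)),
    )


def reconstruct_prefire_sol(
    core: SoilCore, model: ArhModel, plot_mean: float | None = None
) -> float:
    """Pre-fire SOL (cm) for one burned core.

    At-tree cores use the linear ARH relation; away-from-tree cores use the
    plot mean of at-tree reconstructions.
    """
    if core.at_tree:
        if core.arh_ab is None:
            raise ValidationError(f"at-tree core {core.core_id} lacks ARH measurements")
        return model.predict(core.arh_ab)
    if plot_mean is None:
        raise ValidationError(
            f"away-from-tree core {core.core_id} needs a plot mean of at-tree reconstructions"
        )
    return plot_mean


def prefire_soil_carbon(sol_prefire: float, profile: HorizonProfile) -> float:
    """Reconstructed pre-fire organic soil carbon, kg C m^-2."""
    if sol_prefire < 0:
        raise ValidationError("pre-fire SOL must be >= 0")
    return sol_prefire * profile.carbon_per_cm()


def residual_soil_carbon(
    horizons: list[MeasuredHorizon], profile: HorizonProfile | None = None
) -> float:
    """Residual post-fire organic soil carbon, kg C m^-2.

    Horizons with measured depth but missing density or concentration are
    imputed from the profile (with a warning) when one is supplied.
    """
    total = 0.0
    for hz in horizons:
        if hz.depth == 0:
            continue
        rho, conc = hz.bulk_density, hz.c_concentration
        if rho is None or conc is None:
            if profile is None or profile.bulk_density.get(hz.horizon, 0) <= 0:
                raise ValidationError(
                    f"horizon {hz.horizon} has depth but no density/concentration and no profile to impute from"
                )
            log.warning("imputing rho/C for residual horizon %s from profile", hz.horizon)
            rho = rho if rho is not None else profile.bulk_density[hz.horizon]
            conc = conc if conc is not None else profile.c_concentration[hz.horizon]
        total += hz.depth * rho * conc * UNIT_FACTOR
    return total


def core_combustion(prefire: float, postfire: float) -> tuple[float, bool]:
    """max(0, prefire - postfire) with a flag marking a clipped negative value."""
    if prefire < 0 or postfire < 0:
        raise ValidationError("carbon stocks must be >= 0")
    diff = prefire - postfire
    if diff < 0:
        return 0.0, True
    return diff, False


def fit_burndepth_model(
    burn_depths: np.ndarray | list[float], combustion: np.ndarray | list[float]
) -> BurnDepthModel:
    """OLS of core soil combustion on burn depth, pooled over burned cores."""
    x = np.asarray(burn_depths, dtype=float)
    y = np.asarray(combustion, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least two cores to fit the burn-depth model")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all burn depths identical")
    res = stats.linregress(x, y)
    return BurnDepthModel(
        slope=float(res.slope), intercept=float(res.intercept), n=int(x.size), r2=float(res.rvalue**2)
    )


def plot_belowground_combustion(
    core_combustions: list[float],
    outside_depths: list[float],
    depth_model: BurnDepthModel | None,
) -> float:
    """Plot-level belowground combustion, kg C m^-2.

    Average of (1) the mean over transect-core combustion values and (2) the
    mean burn-depth-model prediction at trees outside the transect. Falls back
    to the core mean alone (with a warning) when no outside depths exist.
    """
    if not core_combustions:
        raise ValidationError("no transect cores available")
    core_mean = float(np.mean(core_combustions))
    if not outside_depths or depth_model is None:
        log.warning("no outside-transect burn depths; using transect-core mean alone")
        return core_mean
    outside_mean = float(np.mean([depth_model.predict(d) for d in outside_depths]))
    return 0.5 * (core_mean + outside_mean)
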