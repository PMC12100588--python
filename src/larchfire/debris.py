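"""Downed woody debris carbon via the line-intersect method.

Fine woody debris (FWD, <= 7 cm diameter) is tallied by size class along a
transect line; coarse woody debris (CWD, > 7 cm) is measured piece by piece
with a decay class. The Van Wagner line-intersect estimator converts counts
and diameters to dry mass per unit area, with Brown-style angle and slope
correction factors; carbon follows from a configured debris C concentration,
and plot-level combustion is the pre-fire stock times a visually assigned
consumption fraction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .defaults import CWD_DECAY_DENSITY, DEBRIS_CARBON_FRACTION, FWD_CLASS_PARAMS
from .types import ConfigurationError, DebrisTally, ValidationError


@dataclass
class DebrisParams:
    """Per-class line-intersect constants; densities g cm^-3, QMD cm."""

    fwd_classes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in FWD_CLASS_PARAMS.items()}
    )
    cwd_density: dict[str, float] = field(default_factory=lambda: dict(CWD_DECAY_DENSITY))
    cwd_angle_correction: float = 1.0
    cwd_slope_correction: float = 1.0
    carbon_fraction: float = DEBRIS_CARBON_FRACTION

    def __post_init__(self) -> None:
        for cls, p in self.fwd_classes.items():
            if p["density_g_cm3"] <= 0 or p["qmd_cm"] <= 0:
                raise ConfigurationError(f"non-positive parameter for FWD class {cls}")
            if p["angle_correction"] < 1.0 or p["slope_correction"] < 1.0:
                raise ConfigurationError("correction factors must be >= 1")
        for cls, rho in self.cwd_density.items():
            if rho <= 0:
                raise ConfigurationError(f"non-positive density for decay class {cls}")


def fwd_load(tally: DebrisTally, params: DebrisParams) -> float:
    """FWD dry mass, kg m^-2.

    Van Wagner per size class: pi^2 * rho * n * QMD^2 * a * c / (8 L), with
    QMD converted to m and density to kg m^-3.
    """
    if tally.line_length <= 0:
        raise ValidationError("line length must be > 0")
    total = 0.0
    for cls, n in tally.fwd_counts.items():
        if cls not in params.fwd_classes:
            raise ConfigurationError(f"no parameters for FWD size class {cls!r}")
        p = params.fwd_classes[cls]
        qmd_m = p["qmd_cm"] / 100.0
        rho = p["density_g_cm3"] * 1000.0  # kg m^-3
        total += (
            math.pi**2
            * rho
            * n
            * qmd_m**2
            * p["angle_correction"]
            * p["slope_correction"]
            / (8.0 * tally.line_length)
        )
    return total


def cwd_load(tally: DebrisTally, params: DebrisParams) -> float:
    """CWD dry mass, kg m^-2, from individual piece diameters and decay classes."""
    if tally.line_length <= 0:
        raise ValidationError("line length must be > 0")
    acc = 0.0
    for diameter_cm, decay in tally.cwd_pieces:
        if decay not in params.cwd_density:
            raise ConfigurationError(f"unknown decay class {decay!r}")
        rho = params.cwd_density[decay] * 1000.0
        acc += rho * (diameter_cm / 100.0) ** 2
    return (
        math.pi**2
        * acc
        * params.cwd_angle_correction
        * params.cwd_slope_correction
        / (8.0 * tally.line_length)
    )


def debris_carbon(load_kg_m2: float, params: DebrisParams) -> float:
    """kg C m^-2 from dry mass."""
    return load_kg_m2 * params.carbon_fraction


def debris_combustion(prefire_c: float, consumption_fraction: float) -> float:
    """Pool carbon times the visually assigned consumed fraction."""
    if not 0.0 <= consumption_fraction <= 1.0:
        raise ValidationError("consumption fraction must lie in [0, 1]")
    return prefire_c * consumption_fraction
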