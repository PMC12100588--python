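"""Pre-fire tree biomass and carbon, and canopy combustion from consumption scores.

Each tree's component dry mass (stem wood, stem bark, branches, foliage) is
predicted from its diameter with species-specific power-law equations; where
several equations match, their predictions are averaged. Dry mass converts to
carbon with component-specific concentrations (0.47 wood/bark, 0.48 branches,
0.46 foliage). Canopy combustion translates a 12-point visual consumption
score into per-component consumed fractions via a monotone lookup table.
"""
from __future__ import annotations

import logging

from .defaults import ALLOMETRY_REGISTRY_ROWS, CARBON_FRACTIONS, default_score_table
from .types import (
    COMPONENTS,
    AllometricEquation,
    ComponentBiomass,
    ConfigurationError,
    TreeRecord,
    ValidationError,
)

log = logging.getLogger(__name__)


def default_registry() -> list[AllometricEquation]:
    return [AllometricEquation(**row) for row in ALLOMETRY_REGISTRY_ROWS]


def matching_equations(
    registry: list[AllometricEquation], species: str, component: str, diameter_type: str
) -> list[AllometricEquation]:
    return [
        eq
        for eq in registry
        if eq.species == species and eq.component == component and eq.diameter_type == diameter_type
    ]


def apply_allometry(
    tree: TreeRecord,
    registry: list[AllometricEquation],
    strategy: str = "mean",
) -> ComponentBiomass:
    """Per-component dry mass for one tree.

    ``strategy`` selects how multiple matching equations are combined:
    "mean" (default, arithmetic mean of predictions), "min" or "max"
    (envelope choices used by the uncertainty analysis as structural
    alternatives).
    """
    masses = {}
    for component in COMPONENTS:
        eqs = matching_equations(registry, tree.species, component, tree.diameter_type)
        if not eqs:
            raise ConfigurationError(
                f"no allometric equation for ({tree.species}, {component}, {tree.diameter_type})"
            )
        if all(tree.diameter < eq.d_min or tree.diameter > eq.d_max for eq in eqs):
            log.warning(
                "diameter %.1f cm outside every equation domain for (%s, %s); extrapolating",
                tree.diameter,
                tree.species,
                component,
            )
        preds = [eq.predict(tree.diameter) for eq in eqs]
        if strategy == "mean":
            masses[component] = sum(preds) / len(preds)
        elif strategy == "min":
            masses[component] = min(preds)
        elif strategy == "max":
            masses[component] = max(preds)
        else:
            raise ConfigurationError(f"unknown allometry strategy {strategy!r}")
    return ComponentBiomass(**masses)


def biomass_to_carbon(
    biomass: ComponentBiomass, carbon_fractions: dict[str, float] | None = None
) -> dict[str, float]:
    """kg C per component from kg dry mass."""
    fr = CARBON_FRACTIONS if carbon_fractions is None else carbon_fractions
    return {c: getattr(biomass, c) * fr[c] for c in COMPONENTS}


def validate_score_table(table: dict[int, dict[str, float]]) -> None:
    """A score table must cover scores 1..12 and be monotone per component."""
    for score in range(1, 13):
        if score not in table:
            raise ConfigurationError(f"score table missing score {score}")
        for c in COMPONENTS:
            f = table[score][c]
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("score fractions must lie in [0, 1]")
    for c in COMPONENTS:
        fracs = [table[s][c] for s in range(1, 13)]
        if any(b < a for a, b in zip(fracs, fracs[1:])):
            raise ConfigurationError(f"score table not monotone for component {c}")


def score_to_fractions(
    score: int, table: dict[int, dict[str, float]] | None = None
) -> dict[str, float]:
    if table is None:
        table = default_score_table()
    if not isinstance(score, int) or not 1 <= score <= 12:
        raise ValidationError(f"consumption score {score!r} out of range [1, 12]")
    validate_score_table(table)
    return dict(table[score])


def plot_tree_combustion(
    trees: list[TreeRecord],
    registry: list[AllometricEquation] | None = None,
    score_table: dict[int, dict[str, float]] | None = None,
    area: float = 60.0,
    carbon_fractions: dict[str, float] | None = None,
    strategy: str = "mean",
) -> tuple[float, float]:
    """(combustion, pre-fire tree pool), both kg C m^-2, over one burned transect.

    Sums per-tree, per-component carbon times the consumed fraction implied by
    the tree's consumption score, then normalises by transect area.
    """
    if area <= 0:
        raise ValidationError("transect area must be > 0")
    if registry is None:
        registry = default_registry()
    if score_table is None:
        score_table = default_score_table()
    validate_score_table(score_table)

    consumed = 0.0
    pool = 0.0
    for tree in trees:
        if tree.consumption_score is None:
            raise ValidationError(f"tree in burned plot {tree.plot_id} lacks a consumption score")
        carbon = biomass_to_carbon(apply_allometry(tree, registry, strategy), carbon_fractions)
        fracs = score_table[tree.consumption_score]
        pool += sum(carbon.values())
        consumed += sum(carbon[c] * fracs[c] for c in COMPONENTS)
    return consumed / area, pool / area
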