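"""Shared domain types for the combustion-accounting pipeline.

Units are fixed at the boundary: depths and diameters in cm, bulk density in
g cm^-3, carbon concentration in g C kg^-1, carbon pools and combustion in
kg C m^-2, transect lengths and areas in m and m^2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

FOREST_TYPES = ("larch_dense", "larch_open", "mixed")
BURN_STATUSES = ("burned", "unburned")
MOISTURE_CLASSES = (1, 2, 3)
HORIZONS = ("live_moss", "litter", "lichen", "dead_moss", "fibric", "mesic", "humic")
SPECIES = ("L.cajanderi", "P.sylvestris", "B.pendula", "Alnus", "Salix")
COMPONENTS = ("stem_wood", "stem_bark", "branches", "foliage")
DIAMETER_TYPES = ("DBH", "D0")
SCAR_GROUPS = ("yert_mesic", "yert_no_mesic", "batamay")


class ValidationError(ValueError):
    """A record violates a domain invariant or enumeration."""


class SchemaError(ValueError):
    """A table is missing a required column."""


class ReferenceError_(ValueError):
    """A child record does not resolve to a known plot."""


class ConfigurationError(ValueError):
    """A registry or parameter set does not cover a requested case."""


@dataclass
class Plot:
    """One 30 m x 30 m field plot with its 2 m x 30 m belt transect."""

    plot_id: str
    scar_id: str
    burn_status: str
    forest_type: str
    stand_age: float
    moisture_class: int
    lon: float
    lat: float
    transect_area: float = 60.0
    day_of_burn: str | None = None
    larch_proportion: float | None = None
    x: float | None = None  # projected coordinates in the raster CRS
    y: float | None = None

    def __post_init__(self) -> None:
        if self.burn_status not in BURN_STATUSES:
            raise ValidationError(f"unknown burn_status {self.burn_status!r}")
        if self.forest_type not in FOREST_TYPES:
            raise ValidationError(f"unknown forest_type {self.forest_type!r}")
        if int(self.moisture_class) not in MOISTURE_CLASSES:
            raise ValidationError(f"moisture_class must be in {MOISTURE_CLASSES}")
        if self.transect_area <= 0:
            raise ValidationError("transect_area must be > 0")
        if self.burn_status == "burned" and not self.day_of_burn:
            raise ValidationError(f"burned plot {self.plot_id} lacks day_of_burn")


@dataclass
class FireWeatherRecord:
    """FWI System components plus surface weather for one plot on its day of burn."""

    plot_id: str
    ffmc: float
    dmc: float
    dc: float
    isi: float
    bui: float
    fwi: float
    dsr: float
    temp_c: float
    rh: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh <= 100.0:
            raise ValidationError("RH must be within [0, 100]")
        for name in ("ffmc", "dmc", "dc", "isi", "bui", "fwi", "dsr"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass
class TreeRecord:
    plot_id: str
    species: str
    diameter: float  # cm
    diameter_type: str = "DBH"
    consumption_score: int | None = None  # 1..12, absent on unburned plots

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.diameter <= 0:
            raise ValidationError("diameter must be > 0")
        if self.diameter_type not in DIAMETER_TYPES:
            raise ValidationError(f"unknown diameter_type {self.diameter_type!r}")
        if self.consumption_score is not None and not 1 <= self.consumption_score <= 12:
            raise ValidationError("consumption_score must be in [1, 12]")


@dataclass
class ComponentBiomass:
    """Dry mass per tree component, kg."""

    stem_wood: float
    stem_bark: float
    branches: float
    foliage: float

    def __post_init__(self) -> None:
        for c in COMPONENTS:
            if getattr(self, c) < 0:
                raise ValidationError(f"negative biomass for {c}")

    def total(self) -> float:
        return self.stem_wood + self.stem_bark + self.branches + self.foliage


@dataclass
class AllometricEquation:
    """Diameter-to-component-biomass equation, power law B = a * D^b (kg, cm)."""

    species: str
    component: str
    a: float
    b: float
    diameter_type: str = "DBH"
    source: str = "unspecified"
    d_min: float = 0.0  # stated diameter domain, cm
    d_max: float = float("inf")

    def predict(self, diameter: float) -> float:
        return self.a * diameter**self.b


@dataclass
class DebrisTally:
    """Line-intersect tally of downed wood along one transect line."""

    plot_id: str
    line_length: float = 30.0  # m
    fwd_counts: dict[str, int] = field(default_factory=dict)
    cwd_pieces: list[tuple[float, str]] = field(default_factory=list)  # (diameter cm, decay class)
    consumption_fwd: float | None = None  # fraction, burned plots only
    consumption_cwd: float | None = None

    def __post_init__(self) -> None:
        if self.line_length <= 0:
            raise ValidationError("line_length must be > 0")
        for cls, n in self.fwd_counts.items():
            if n < 0:
                raise ValidationError(f"negative count for FWD class {cls}")
        for d, _ in self.cwd_pieces:
            if d <= 7.0:
                raise ValidationError("CWD pieces must have diameter > 7 cm")
        for frac in (self.consumption_fwd, self.consumption_cwd):
            if frac is not None and not 0.0 <= frac <= 1.0:
                raise ValidationError("consumption fractions must lie in [0, 1]")


@dataclass
class MeasuredHorizon:
    """A residual organic soil horizon measured in a core."""

    horizon: str
    depth: float  # cm
    bulk_density: float | None = None  # g cm^-3
    c_concentration: float | None = None  # g C kg^-1

    def __post_init__(self) -> None:
        if self.horizon not in HORIZONS:
            raise ValidationError(f"unknown horizon {self.horizon!r}")
        if self.depth < 0:
            raise ValidationError("horizon depth must be >= 0")
        if self.depth > 0 and self.bulk_density is not None and self.bulk_density <= 0:
            raise ValidationError("bulk density must be > 0 where depth > 0")


@dataclass
class SoilCore:
    plot_id: str
    core_id: str
    position: float  # m along transect
    at_tree: bool
    horizons: list[MeasuredHorizon] = field(default_factory=list)
    sol: float | None = None  # residual organic depth, cm
    arh0: float | None = None  # uppermost adventitious root below surface, cm
    sol_prefire: float | None = None  # reconstructed, cm

    @property
    def arh_ab(self) -> float | None:
        """Adventitious root height above mineral soil: SOL - ARH_0 (cm)."""
        if self.sol is None or self.arh0 is None:
            return None
        return self.sol - self.arh0

    @property
    def burn_depth(self) -> float | None:
        """Reconstructed pre-fire SOL minus residual SOL, clipped at zero (cm)."""
        if self.sol_prefire is None or self.sol is None:
            return None
        return max(0.0, self.sol_prefire - self.sol)

    def horizon_depth_total(self) -> float:
        return sum(h.depth for h in self.horizons)


@dataclass
class ArhModel:
    """Linear pre-fire surface reconstruction SOL = slope * ARH_ab + intercept."""

    slope: float = 0.96
    intercept: float = 3.91  # cm
    n: int = 0
    r2: float | None = None
    resid_sd: float | None = None

    def predict(self, arh_ab: float) -> float:
        return self.slope * arh_ab + self.intercept


@dataclass
class HorizonProfile:
    """Per (forest type, scar group) fractional depths and horizon properties."""

    forest_type: str
    scar_group: str
    frac_depth: dict[str, float]
    bulk_density: dict[str, float]  # g cm^-3
    c_concentration: dict[str, float]  # g C kg^-1
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.frac_depth.values())
        if abs(total - 1.0) > 0.01:
            raise ValidationError(
                f"fractional depths for ({self.forest_type}, {self.scar_group}) "
                f"sum to {total:.3f}, expected 1 +/- 0.01"
            )
        for hz, f in self.frac_depth.items():
            if hz not in HORIZONS:
                raise ValidationError(f"unknown horizon {hz!r}")
            if f < 0:
                raise ValidationError("fractional depth must be >= 0")
            if f > 0:
                if self.bulk_density.get(hz, 0.0) <= 0:
                    raise ValidationError(f"missing/non-positive bulk density for {hz}")
                if self.c_concentration.get(hz, 0.0) <= 0:
                    raise ValidationError(f"missing/non-positive C concentration for {hz}")

    def carbon_per_cm(self) -> float:
        """kg C m^-2 of reconstructed soil column per cm of pre-fire depth."""
        return sum(
            f * self.bulk_density[hz] * self.c_concentration[hz] / 100.0
            for hz, f in self.frac_depth.items()
            if f > 0
        )


@dataclass
class CombustionMetrics:
    """Per-plot absolute and relative combustion with pool breakdown."""

    plot_id: str
    ca: float  # aboveground, kg C m^-2
    cb: float  # belowground
    ct: float  # total
    pca: float | None  # fractions of pre-fire pools; None where pool is zero
    pcb: float | None
    pct: float | None
    pool_breakdown: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in (self.ca, self.cb, self.ct):
            if v < -1e-9:
                raise ValidationError("absolute combustion must be >= 0")
        if abs(self.ct - (self.ca + self.cb)) > 1e-6:
            raise ValidationError("Ct must equal Ca + Cb")
        for p in (self.pca, self.pcb, self.pct):
            if p is not None and not -1e-9 <= p <= 1 + 1e-9:
                raise ValidationError("relative combustion must lie in [0, 1]")


@dataclass
class Campaign:
    """A fully cross-referenced field campaign."""

    plots: dict[str, Plot]
    trees: list[TreeRecord] = field(default_factory=list)
    debris: dict[str, DebrisTally] = field(default_factory=dict)
    cores: list[SoilCore] = field(default_factory=list)
    weather: dict[str, FireWeatherRecord] = field(default_factory=dict)
    outside_depths: dict[str, list[float]] = field(default_factory=dict)  # cm, per plot

    def burned_plots(self) -> list[Plot]:
        return [p for p in self.plots.values() if p.burn_status == "burned"]

    def unburned_plots(self) -> list[Plot]:
        return [p for p in self.plots.values() if p.burn_status == "unburned"]

    def plot_trees(self, plot_id: str) -> list[TreeRecord]:
        return [t for t in self.trees if t.plot_id == plot_id]

    def plot_cores(self, plot_id: str) -> list[SoilCore]:
        return [c for c in self.cores if c.plot_id == plot_id]
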