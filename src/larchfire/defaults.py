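"""Default parameter sets for the pipeline.

The horizon parameter table reproduces the unburned-plot organic-soil
characterisation by forest type and fire-scar group (fractional depths, bulk
densities in g cm^-3, carbon concentrations in g C kg^-1). Mesic-horizon
density and concentration were characterised on burned plots (mesic layers
are rare in unburned stands) and carry a provenance tag.

The allometric-equation registry and the consumption-score mapping are
editable data, not code: the shipped entries are provisional literature-style
power laws and a linear score ramp, intended to be replaced by a user's own
calibrated registry where available.
"""
from __future__ import annotations

# --- Horizon parameter table -------------------------------------------------
# columns: forest_type, scar_group, horizon, frac_depth, bulk_density, c_concentration
HORIZON_PARAM_ROWS: list[tuple[str, str, str, float, float, float]] = [
    # larch_dense, Yert (no mesic horizon present)
    ("larch_dense", "yert_no_mesic", "live_moss", 0.06, 0.016, 401.6),
    ("larch_dense", "yert_no_mesic", "litter", 0.29, 0.036, 422.9),
    ("larch_dense", "yert_no_mesic", "dead_moss", 0.39, 0.045, 371.4),
    ("larch_dense", "yert_no_mesic", "fibric", 0.26, 0.153, 258.7),
    ("larch_dense", "yert_no_mesic", "mesic", 0.00, 0.534, 69.9),
    # larch_dense, Batamay (no live moss; thin dead moss)
    ("larch_dense", "batamay", "live_moss", 0.00, 0.016, 401.6),
    ("larch_dense", "batamay", "litter", 0.37, 0.036, 422.9),
    ("larch_dense", "batamay", "dead_moss", 0.05, 0.045, 371.4),
    ("larch_dense", "batamay", "fibric", 0.58, 0.153, 258.7),
    ("larch_dense", "batamay", "mesic", 0.00, 0.534, 69.9),
    # larch_open, Yert
    ("larch_open", "yert_no_mesic", "live_moss", 0.02, 0.016, 401.6),
    ("larch_open", "yert_no_mesic", "litter", 0.23, 0.036, 422.9),
    ("larch_open", "yert_no_mesic", "dead_moss", 0.33, 0.072, 371.4),
    ("larch_open", "yert_no_mesic", "fibric", 0.42, 0.153, 258.7),
    ("larch_open", "yert_no_mesic", "mesic", 0.00, 0.534, 69.9),
    # larch_open, Batamay
    ("larch_open", "batamay", "live_moss", 0.00, 0.016, 401.6),
    ("larch_open", "batamay", "litter", 0.37, 0.036, 422.9),
    ("larch_open", "batamay", "dead_moss", 0.05, 0.072, 371.4),
    ("larch_open", "batamay", "fibric", 0.58, 0.153, 258.7),
    ("larch_open", "batamay", "mesic", 0.00, 0.534, 69.9),
    # mixed larch/pine, Yert with mesic horizon
    ("mixed", "yert_mesic", "live_moss", 0.00, 0.016, 401.6),
    ("mixed", "yert_mesic", "litter", 0.68, 0.063, 422.9),
    ("mixed", "yert_mesic", "dead_moss", 0.00, 0.057, 371.4),
    ("mixed", "yert_mesic", "fibric", 0.25, 0.296, 169.7),
    ("mixed", "yert_mesic", "mesic", 0.07, 0.254, 182.0),
    # mixed larch/pine, Yert without mesic
    ("mixed", "yert_no_mesic", "live_moss", 0.05, 0.016, 401.6),
    ("mixed", "yert_no_mesic", "litter", 0.42, 0.063, 422.9),
    ("mixed", "yert_no_mesic", "dead_moss", 0.05, 0.057, 371.4),
    ("mixed", "yert_no_mesic", "fibric", 0.48, 0.296, 169.7),
    ("mixed", "yert_no_mesic", "mesic", 0.00, 0.254, 182.0),
]

MESIC_FROM_BURNED_PLOTS = True  # provenance flag for mesic rho and C entries

# --- Carbon concentrations of tree components (fraction of dry mass) ---------
CARBON_FRACTIONS: dict[str, float] = {
    "stem_wood": 0.47,
    "stem_bark": 0.47,
    "branches": 0.48,
    "foliage": 0.46,
}

DEBRIS_CARBON_FRACTION = 0.47  # same default as stem wood

# --- Allometric equation registry (provisional literature-style values) ------
# Power laws B = a * D^b with B in kg dry mass and D in cm. Two independent
# sources are listed for larch stem wood so equation averaging is exercised.
ALLOMETRY_REGISTRY_ROWS: list[dict] = [
    # Cajander larch, DBH-based
    {"species": "L.cajanderi", "component": "stem_wood", "a": 0.0458, "b": 2.47, "diameter_type": "DBH", "source": "siberia-natural-A", "d_min": 0.5, "d_max": 60.0},
    {"species": "L.cajanderi", "component": "stem_wood", "a": 0.0520, "b": 2.42, "diameter_type": "DBH", "source": "siberia-natural-B", "d_min": 0.5, "d_max": 60.0},
    {"species": "L.cajanderi", "component": "stem_bark", "a": 0.0148, "b": 2.20, "diameter_type": "DBH", "source": "siberia-natural-A", "d_min": 0.5, "d_max": 60.0},
    {"species": "L.cajanderi", "component": "branches", "a": 0.0117, "b": 2.36, "diameter_type": "DBH", "source": "siberia-natural-A", "d_min": 0.5, "d_max": 60.0},
    {"species": "L.cajanderi", "component": "foliage", "a": 0.0169, "b": 1.79, "diameter_type": "DBH", "source": "siberia-natural-A", "d_min": 0.5, "d_max": 60.0},
    # Cajander larch, basal-diameter form for stems < 1.3 m tall
    {"species": "L.cajanderi", "component": "stem_wood", "a": 0.0249, "b": 2.32, "diameter_type": "D0", "source": "siberia-sapling", "d_min": 0.1, "d_max": 8.0},
    {"species": "L.cajanderi", "component": "stem_bark", "a": 0.0080, "b": 2.10, "diameter_type": "D0", "source": "siberia-sapling", "d_min": 0.1, "d_max": 8.0},
    {"species": "L.cajanderi", "component": "branches", "a": 0.0068, "b": 2.25, "diameter_type": "D0", "source": "siberia-sapling", "d_min": 0.1, "d_max": 8.0},
    {"species": "L.cajanderi", "component": "foliage", "a": 0.0110, "b": 1.70, "diameter_type": "D0", "source": "siberia-sapling", "d_min": 0.1, "d_max": 8.0},
    # Scots pine
    {"species": "P.sylvestris", "component": "stem_wood", "a": 0.0428, "b": 2.43, "diameter_type": "DBH", "source": "schepaschenko-fit", "d_min": 0.5, "d_max": 60.0},
    {"species": "P.sylvestris", "component": "stem_bark", "a": 0.0132, "b": 2.18, "diameter_type": "DBH", "source": "schepaschenko-fit", "d_min": 0.5, "d_max": 60.0},
    {"species": "P.sylvestris", "component": "branches", "a": 0.0094, "b": 2.41, "diameter_type": "DBH", "source": "schepaschenko-fit", "d_min": 0.5, "d_max": 60.0},
    {"species": "P.sylvestris", "component": "foliage", "a": 0.0230, "b": 1.86, "diameter_type": "DBH", "source": "schepaschenko-fit", "d_min": 0.5, "d_max": 60.0},
    # Silver birch
    {"species": "B.pendula", "component": "stem_wood", "a": 0.0508, "b": 2.45, "diameter_type": "DBH", "source": "n-europe-managed", "d_min": 0.5, "d_max": 40.0},
    {"species": "B.pendula", "component": "stem_bark", "a": 0.0124, "b": 2.29, "diameter_type": "DBH", "source": "n-europe-managed", "d_min": 0.5, "d_max": 40.0},
    {"species": "B.pendula", "component": "branches", "a": 0.0077, "b": 2.53, "diameter_type": "DBH", "source": "n-europe-managed", "d_min": 0.5, "d_max": 40.0},
    {"species": "B.pendula", "component": "foliage", "a": 0.0098, "b": 1.93, "diameter_type": "DBH", "source": "n-europe-managed", "d_min": 0.5, "d_max": 40.0},
    # Alder and willow shrubs, basal diameter
    {"species": "Alnus", "component": "stem_wood", "a": 0.0376, "b": 2.31, "diameter_type": "D0", "source": "shrub-generic", "d_min": 0.1, "d_max": 12.0},
    {"species": "Alnus", "component": "stem_bark", "a": 0.0091, "b": 2.11, "diameter_type": "D0", "source": "shrub-generic", "d_min": 0.1, "d_max": 12.0},
    {"species": "Alnus", "component": "branches", "a": 0.0149, "b": 2.26, "diameter_type": "D0", "source": "shrub-generic", "d_min": 0.1, "d_max": 12.0},
    {"species": "Alnus", "component": "foliage", "a": 0.0121, "b": 1.76, "diameter_type": "D0", "source": "shrub-generic", "d_min": 0.1, "d_max": 12.0},
    {"species": "Salix", "component": "stem_wood", "a": 0.0330, "b": 2.28, "diameter_type": "D0", "source": "shrub-generic", "d_min": 0.1, "d_max": 12.0},
    {"species": "Salix", "component": "stem_bark", "a": 0.0085, "b": 2.08, "diameter_type": "D0", "source": "shrub-generic", "d_min": 0.1, "d_max": 12.0},
    {"species": "Salix", "component": "branches", "a": 0.0133, "b": 2.22, "diameter_type": "D0", "source": "shrub-generic", "d_min": 0.1, "d_max": 12.0},
    {"species": "Salix", "component": "foliage", "a": 0.0102, "b": 1.72, "diameter_type": "D0", "source": "shrub-generic", "d_min": 0.1, "d_max": 12.0},
]

# --- Consumption-score mapping -----------------------------------------------
# 12-point visual canopy-consumption scale translated to fractional consumption
# per component. Shipped default is a linear ramp from 0 at score 1 to a
# component-specific maximum at score 12 (foliage and branches can be fully
# consumed; stem wood rarely is). Provisional: any monotone table is accepted.
SCORE_MAX_FRACTIONS: dict[str, float] = {
    "stem_wood": 0.25,
    "stem_bark": 0.60,
    "branches": 1.00,
    "foliage": 1.00,
}


def default_score_table() -> dict[int, dict[str, float]]:
    """Linear score -> per-component consumption-fraction ramp."""
    table: dict[int, dict[str, float]] = {}
    for score in range(1, 13):
        ramp = (score - 1) / 11.0
        table[score] = {c: ramp * fmax for c, fmax in SCORE_MAX_FRACTIONS.items()}
    return table


# --- Line-intersect debris parameters ----------------------------------------
# FWD size classes follow the usual timelag-style diameter bins (cm). QMD is
# the quadratic mean diameter of the class; densities are sound-wood defaults.
# Correction factors: a = non-horizontal angle correction, c = slope correction.
FWD_CLASS_PARAMS: dict[str, dict[str, float]] = {
    "fwd_0_0.5": {"qmd_cm": 0.35, "density_g_cm3": 0.48, "angle_correction": 1.13, "slope_correction": 1.0},
    "fwd_0.5_1": {"qmd_cm": 0.75, "density_g_cm3": 0.48, "angle_correction": 1.13, "slope_correction": 1.0},
    "fwd_1_3": {"qmd_cm": 1.85, "density_g_cm3": 0.44, "angle_correction": 1.13, "slope_correction": 1.0},
    "fwd_3_7": {"qmd_cm": 4.60, "density_g_cm3": 0.40, "angle_correction": 1.13, "slope_correction": 1.0},
}

# CWD decay-class wood densities (g cm^-3), sound -> rotten
CWD_DECAY_DENSITY: dict[str, float] = {
    "sound": 0.42,
    "intermediate": 0.32,
    "rotten": 0.22,
}
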