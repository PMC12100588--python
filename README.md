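# larchfire

Carbon combustion accounting for fires in boreal larch (*Larix*) forests.

Fires in eastern Siberian larch stands release carbon from two very
different stores: the canopy and downed wood aboveground, and thick organic
soil layers belowground. Quantifying how much burned requires reconstructing
what was there *before* the fire from what is measurable *after* it.
`larchfire` is a tested, reusable pipeline for exactly that accounting,
aimed at fire ecologists and carbon-cycle modellers working with plot-based
combustion campaigns:

- **Aboveground pools** — per-tree component biomass from diameter-based
  allometric power laws B = a·D^b, converted to carbon (0.47 stem wood/bark,
  0.48 branches, 0.46 foliage), with canopy combustion from a 12-point visual
  consumption score; downed-wood loads from the Van Wagner line-intersect
  estimator π²ρnQMD²ac/(8L).
- **Belowground pools** — the pre-fire soil surface at burned cores is
  recovered from adventitious root heights via SOL = 0.96·ARH_ab + 3.91 (cm,
  refitted from controls when available); pre-fire soil carbon per core is
  SOL_pre · Σ_hz frac_hz·ρ_hz·C_hz/100 (kg C m⁻²), residual carbon is the
  measured horizon sum, and combustion is the difference, clipped at zero.
  Plot values average the transect cores with a burn-depth regression applied
  at trees outside the transect.
- **Uncertainty** — a 1000-run Monte Carlo perturbs eleven named error
  sources (parameters and method switches) and attributes the resulting
  spread to the tree, debris, and soil pools via "source removed" /
  "source only" scenarios with common random numbers.
- **Drivers** — candidate linear models of plot attributes, stand
  composition, and fire weather (FWI, VPD) ranked by
  AICc = −2logL + 2K + 2K(K+1)/(n−K−1) with Akaike weights.
- **Upscaling** — plot combustion regressed on raster predictors (slope,
  dNBR, percent sand), validated by repeated 10-fold cross validation, and
  predicted over fire-scar perimeters with per-pixel Monte Carlo uncertainty.
- **Synthetic campaigns** — a generator with a known-truth ledger emulates
  the whole study design (three forest types, horizon stratigraphy, the
  ARH–SOL relation, weather-linked burn depth, linked raster stacks), so
  every estimator can be checked against ground truth.

## Worked example

```python
from larchfire import synthetic, pipeline, uncertainty

campaign, ledger = synthetic.generate_campaign(seed=42)
results = pipeline.process_campaign(campaign)
print(f"plots: {len(results)}")
print(f"pre-fire pools: above {results['prefire_above'].mean():.2f}, "
      f"below {results['prefire_below'].mean():.2f} kg C m^-2")
print(f"combustion: total {results['ct'].mean():.2f}, "
      f"above {results['ca'].mean():.2f}, below {results['cb'].mean():.2f} kg C m^-2")
print(f"belowground share: {100*results['cb'].mean()/results['ct'].mean():.0f}%")

compiled = pipeline.compile_campaign(campaign)
mc = uncertainty.run_mc(compiled, n_sims=1000, seed=0)
print(f"MC uncertainty (SD of campaign mean, 1000 runs): {mc.summary['ct']['sd']:.2f} kg C m^-2")
```

prints

```
plots: 41
pre-fire pools: above 3.14, below 3.77 kg C m^-2
combustion: total 3.24, above 0.92, below 2.33 kg C m^-2
belowground share: 72%
MC uncertainty (SD of campaign mean, 1000 runs): 0.59 kg C m^-2
```

i.e., on this synthetic 41-plot campaign the fires consumed 3.24 kg C m⁻² on
average, 72% of it from organic soils, with a Monte Carlo uncertainty of
0.59 kg C m⁻² on the campaign mean — magnitudes typical of severe fires in
these ecosystems.

A command-line interface mirrors the library
(`larchfire simulate|reconstruct|combust|uncertainty|drivers|upscale`, each
taking `--config <yaml> --seed <int> --out <dir>`); tables are CSV, rasters
are plain-text ESRI ASCII grids with a `.prj` sidecar, perimeters are
GeoJSON polygons.

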