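# Methods

`larchfire` implements a complete carbon-combustion accounting chain for
burned boreal larch forest plots: reconstruction of pre-fire aboveground and
belowground carbon pools, per-pool combustion estimation, Monte Carlo
uncertainty attribution, AICc-based driver-model ranking, and regression
upscaling over fire-scar rasters. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Pool reconstruction and combustion accounting

**Trees.** Every stem on the 2 m x 30 m belt transect carries a diameter
(DBH for stems taller than 1.3 m, basal diameter D0 otherwise) and, on burned
plots, a 12-point visual consumption score. Component dry mass (stem wood,
stem bark, branches, foliage) comes from species-specific power laws
B = a D^b; when several equations match a (species, component, diameter-type)
triple their predictions are averaged. Averaging before or after carbon
conversion is equivalent because the carbon concentrations (0.47 for stem
wood and bark, 0.48 for branches, 0.46 for foliage) are linear factors; the
implementation averages mass first. The shipped equation registry contains
provisional literature-style coefficients and is data, not code — users with
locally calibrated equations should replace it. The score-to-consumed-fraction
table is likewise a configurable default: a linear ramp from zero at score 1
to component maxima at score 12 (foliage and branches 1.0, stem bark 0.6,
stem wood 0.25). Any monotone table is accepted; non-monotone tables are
rejected at load.

**Downed wood.** Fine woody debris (diameter <= 7 cm) is tallied by size
class and converted to mass per area with the Van Wagner line-intersect
estimator, pi^2 rho n QMD^2 a c / (8L), using per-class quadratic mean
diameters, wood densities, and Brown-style angle (default 1.13) and slope
(default 1.0) corrections. Coarse pieces (> 7 cm) enter individually with
decay-class densities (0.42/0.32/0.22 g cm^-3 sound/intermediate/rotten).
Debris carbon uses the stem-wood concentration (0.47) by default. Plot-level
debris combustion is the pre-fire stock times a visually assigned consumed
fraction.

**Organic soil.** The pre-fire soil surface at a burned core next to a tree
is recovered from the adventitious root height above mineral soil,
SOL = 0.96 ARH_ab + 3.91 (cm); the relation is refitted by OLS whenever at
least three unburned at-tree cores are available, and falls back to those
published coefficients otherwise (enabling burned-only reanalysis). Cores
away from trees take the plot mean of at-tree reconstructions, using
same-plot cores only. Pre-fire soil carbon per core is

    C_pre = SOL_pre * sum_hz frac_hz * rho_hz * C_hz / 100   [kg C m^-2]

with fractional depths, bulk densities (g cm^-3), and carbon concentrations
(g C kg^-1) taken from unburned-plot profiles per forest type and scar group;
the 1/100 factor is the single unit conversion in the chain and is pinned by
a dimensional test fixture. Residual carbon is the measured per-horizon sum
(same convention). Core combustion is the difference, clipped at zero
because negative combustion is physically impossible; clipping is applied at
core level, before plot averaging, and every clip event is counted and
logged. Mesic-horizon density and concentration derive from burned plots
(mesic layers are rare in controls) and carry a provenance flag.

**Plot belowground combustion** averages (1) the transect-core mean with
(2) the mean prediction of a pooled linear burn-depth-to-combustion transfer
model applied at ten trees outside the transect. The transfer model is fitted
on all burned cores pooled across scars. When no outside depths exist the
core mean is used alone, with a warning. The plot value is constrained to
[0, pre-fire pool]: the outside-tree regression can otherwise produce small
negative values under extreme parameter perturbations, and the same
physical-impossibility argument that motivates core-level clipping applies.

## Monte Carlo uncertainty

Eleven named error sources perturb the chain: equation-combination choice,
tree carbon concentrations (one systematic normal shift with SD 3 percentage
points applied to all components), the score-ramp shape, FWD and CWD
line-intersect parameters, debris carbon concentration, debris consumption
fractions, the ARH model coefficients, unburned-profile density and
concentration, and the two method switches (core clipping level, outside-tree
averaging). Parameter sources draw from normal distributions; method switches
draw uniformly over their alternatives. All SDs except the tree-carbon value
are editable, provisional defaults. A 1000-run ensemble re-executes the full
pipeline per draw; uncertainty is the SD of the campaign-mean combustion.

Source attribution freezes a pool's sources ("source removed") or everything
else ("source only"). One master seed spawns an independent substream per
(run, source) keyed by position in the spec list, so all scenario families
share common random numbers: freezing a source leaves every other draw
bit-identical. This coupling is a deliberate design choice — it sharpens
attribution contrasts at no cost to the marginal distributions — and it makes
the single-source identities (sd_only = sd_all, sd_removed = 0) hold exactly
rather than statistically.

## Driver analysis

Six responses (absolute and relative aboveground, belowground, and total
combustion) are regressed on candidate models encoding plot attributes
(M1: stand age, pre-fire SOL, 3-level condensed moisture class), stand
composition (M2: pre-fire tree biomass, larch proportion), fire weather
(M3: FWI), their unions (M4–M6), the full union, and a null model. Models are
ranked by AICc = -2 logL + 2K + 2K(K+1)/(n-K-1) with Akaike weights. K counts
the intercept, slope terms, factor dummy levels, and the residual variance;
with the moisture class coded as a 3-level factor this yields the ladder
Null 2, M3 3, M2 4, M6 5, M1 6, M5 7, M4 8, Full 9 — the only K composition
consistent with that sequence, which is why it is fixed in code rather than
configurable. Aboveground responses are power-ladder transformed (lambda =
0.35 absolute, 0.45 relative) before fitting. Collinearity screening drops,
from each pair with Spearman p < 0.05, the member with the weaker rank
correlation to the response; the pair, rho, p, and the dropped member are
reported so reruns are auditable. Vapor pressure deficit is computed as
(1 - RH/100) * 0.6107 * 10^(7.5T/(T+237.3)) kPa.

## Spatial upscaling

Plot-level predictor values are area-weighted means of the 30 m pixels
intersecting each 30 m x 30 m plot square, with nodata pixels excluded from
the weights. Selection proceeds per predictor set (collinearity screen, OLS,
keep p < 0.05 terms) and then reduces the pooled model by backward stepwise
AIC; when nothing is significant an explicitly flagged intercept-only model
is returned rather than an error, since a map can still be produced.
Generalisation is checked by 10-fold cross validation repeated 100 times
(mean over repetitions of R^2 on pooled out-of-fold predictions).

The uncertainty map re-runs the chain 1000 times: per simulation each plot's
per-pool combustion is shifted by z times its plot-level SD, the model is
refitted, every in-perimeter pixel is predicted, and an i.i.d. residual-error
draw is added per pixel (no spatial autocorrelation in the residual field).
Refitting re-estimates coefficients for the selected predictor labels;
re-running the full selection per simulation is available behind a flag but
is off by default, reading "a new regression model per simulation" as
re-estimation rather than re-selection. Negative pixel predictions (which
occur on steep stream banks in real data) are retained and counted; an
optional floor-at-zero flag exists, default off.

**Raster format.** Grids are single-band, north-up, square-pixel rasters
carried as plain-text ESRI ASCII grids (.asc) with an optional .prj sidecar
for the CRS tag. This keeps every artifact diffable and round-trip exact;
reprojection and rotated transforms are out of scope, and bilinear regridding
(which preserves constant fields exactly) is the only resampling offered.

## Synthetic campaign generator

The generator is first-class, tested code, and its defaults define the study
conditions: 41 burned plots (17 dense / 20 open / 4 mixed) plus 12 controls
(6/3/3); stand densities 24,700 and 10,900 stems ha^-1 and mean ages
55/112/131 y for dense/open/mixed; mean burn depths 8.0/10.0/10.9 cm; the
default horizon-parameter table per forest type and scar group; and the ARH
relation (0.96, 3.91) with 1 cm residual scatter. Log-normal diameter medians
(3.0/4.6/5.2 cm, sigma 0.45–0.5) were chosen once so pre-fire pools land near
3.1 (aboveground) and 3.5 (belowground) kg C m^-2, the magnitudes typical of
these stands. A per-plot severity latent, partly driven by FWI, links burn
depth, canopy consumption scores, and debris consumption, so aboveground and
belowground severity co-vary as crown-fire observations imply. Five cores per
plot (two away from trees) realise the horizon stack of their profile at a
drawn pre-fire depth; burned cores are truncated from the top by the drawn
burn depth. The truth ledger records per-core pre-fire, residual, and
combusted carbon from the same realised stack, so conservation holds exactly
by construction and no truth value is ever clipped.

Raster stacks (slope, dNBR, percent sand; 60 x 60 pixels at 30 m per scar)
are smooth random fields; the dNBR field is locally pinned to each plot's
severity so field combustion and remote-sensing severity correlate, and true
pixel combustion follows a configured linear link (default intercept 1.0,
slopes -0.08/0.006/-0.01) plus optional noise. Fire perimeters are irregular
quadrilaterals inset from the grid edge; generation fails loudly if a plot
falls outside its perimeter or if a configured burn depth exceeds the soil
depth it is supposed to burn into.

**What the generator does not emulate:** spatial autocorrelation of soils and
fuels beyond the raster link, measurement error in diameters and tallies,
discrete GFWED grid-cell structure in fire weather (each plot draws its own
weather), snag dynamics, and post-fire recovery. Passing recovery tests
therefore demonstrates internal consistency of the estimators under the
assumed error structure, not robustness to every failure mode of real field
data.

## Numerical choices and limitations

- OLS fits use statsmodels (driver and spatial models) or closed-form
  normal equations (inside the Monte Carlo loops, for speed); the two paths
  agree to machine precision on shared problems.
- The burn-depth transfer model inside the MC loop is refitted per run from
  that run's core values, so its uncertainty propagates.
- Relative-combustion metrics are undefined (flagged missing, not zero) when
  the corresponding pre-fire pool is zero.
- Ties in backward selection are broken by first-improvement in list order;
  prediction is invariant to predictor ordering.
- Problem sizes used by the shipped analyses: 41-plot campaigns, 1000-run
  ensembles, 60 x 60-pixel scars, 10-fold x 100 cross validation. All scale
  linearly in their obvious dimensions.
- The packaged allometry registry, score ramp, debris constants, and MC
  source SDs are provisional stand-ins pending locally calibrated values;
  each is data/configuration, flagged as such where it is defined.
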