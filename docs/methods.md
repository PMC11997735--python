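# Methods

This note documents the models and procedures `mpatrack` implements, the
defaults it ships, the numerical conventions it commits to, and what the
synthetic test world can and cannot establish about real tracking data.

## Geometry

All distances are great-circle distances on a sphere of radius
6371.0088 km. Longitudes live in [−180, 180) and are unwrapped locally for
interpolation near the antimeridian. Planar work (kernel densities,
isopleth areas, spatial blocks) uses an azimuthal-equidistant projection
centred on the colony/tagging site: radial distances from the centre are
exact, which keeps kernel bandwidths and isopleth areas meaningful at
home-range scale and lets area estimates be validated against closed
forms. A degree-based grid would distort areas at the scale of pelagic
movements.

## Track processing

Cleaning follows standard multi-tag practice, with the boundary
conventions fixed once:

- **Deployment trimming** keeps fixes in [start, end] inclusive.
- **Speed filter**: iterative; a fix is dropped when its implied speed
  from the previous *retained* fix exceeds the species vmax, so a single
  teleporting outlier does not cascade. The first fix is always kept.
- **Colony removal** (central-place foragers) drops fixes strictly within
  5 km of the colony; **trip segmentation** keeps maximal runs strictly
  beyond 5 km lasting at least the species minimum (1 h or 6 h). "Within"
  uses `<`, "beyond" uses `>`, matching the wording of each rule.
- **Regularization** emits fixes evenly spaced at the tag's nominal
  interval by great-circle interpolation between bracketing raw fixes.
  State-space-model resampling is deliberately replaced by this
  deterministic interpolation with the same even-spacing contract: the
  downstream unit is the daily median, which is insensitive to within-day
  smoothing, and determinism makes the stage testable. Gaps longer than
  20 days are never interpolated across; the segments remain one track
  for identity but restart the regular clock.
- **Daily geodesic median**: per local day — a fixed UTC−10 (HST)
  24-hour bin, no daylight saving — the point minimizing the summed
  great-circle distance to the day's fixes, by Riemannian Weiszfeld
  iteration (tolerance 1e−10 rad, ≤ 1000 iterations; non-convergence
  falls back to the best raw fix and is flagged). A distance floor of
  1e−12 rad guards the 1/d weights when the estimate lands on a data
  point.
- **Zone accounting**: a polygon boundary counts as *inside* everywhere —
  the conservative choice when crediting a protected area. The headline
  "% of movements inside" is the mean over individuals of each
  individual's daily-location fraction (per-individual values are also
  exposed, so pooled aggregation is one `groupby` away).

## Space use

UDs use a bivariate normal product kernel on a 150×150 grid spanning the
points' bounding box padded by 1° (≈ 111 km per side), with the classical
reference bandwidth h_ref = ½(σ_x + σ_y)·n^(−1/6) in projected km. The
padding-not-cell-size reading of the grid "extent" is deliberate: the 150
intervals define the cells. Density is renormalized to unit mass on the
finite grid. Isopleths take cells in descending density order (ties broken
by flat cell index) until the target mass is reached; area is cell count ×
cell area. UDs require ≥ 5 points; partitions below that are reported as
missing, mirroring dashed table entries for data-poor species. On 10,000
draws from a circular Gaussian with σ = 50 km the 50% isopleth area is
within 3% of the closed form 2πσ²ln2 (the test tolerance is 10%).

## Pseudo-absences

Background sampling is uniform over each individual's dateline-aware
track bounding box. CRW simulation resamples step lengths and turning
angles independently with replacement (the two marginals are specified;
no joint structure is claimed), starts at the observed start point with a
uniform initial heading, and preserves track length; individuals with
fewer than 3 locations fall back to background-only. One of the 100
simulations is drawn at random and date-matched 1:1 to presence days
(k-th simulated point ↔ k-th presence day), preserving the temporal
pairing that monthly covariate annotation needs. Simulated points are not
land-masked by default (a bathymetry mask is available but off).
Bhattacharyya coefficients use shared equal-width bins over the pooled
range, with ceil(√min(n_p, n_q)) bins clipped to [5, 50]; a zero pooled
range returns 1 by convention.

## Environmental covariates

Stacks carry monthly SST, chlorophyll-a, dissolved surface oxygen, and
current u/v plus static bathymetry; speed = √(u² + v²) and heading =
atan2(v, u) are derived cellwise (heading in radians internally).
Annotation is nearest-cell per axis with midpoint ties to the lower
index, in the monthly layer containing the point's date; climatology
stacks match by calendar month. Rows outside the grid or calendar get an
explicit missing flag and are excluded from fitting (complete-case) with
a count. Standardization is (x − mean)/SD with parameters computed on the
fitting table and stored on the model; prediction — including on future
fields — reuses them unchanged, because a historically trained model must
score future conditions on the historical scale. Climatologies are
two-stage medians: per source dataset, the median per calendar month per
cell over the year range; then the median across datasets.

## Habitat models

Boosted regression trees (gradient boosting with bernoulli/log loss)
with learning rate 0.005, interaction depth 5, 2000 trees, bag fraction
0.75 — the settings long established for ecological presence/absence
work. Relative influence is the per-covariate share of total
split-improvement, scaled to 100. AUC uses the rank formulation with
ties counted ½; TSS is max over thresholds of sensitivity +
specificity − 1 (the common SDM convention — the threshold is otherwise
unidentified); R² is deviance explained, 1 − D_model/D_null, the natural
binomial reading. Ten-fold CV is stratified by label; spatial block CV
tiles the points' planar extent with square blocks of the configured area
(e.g., 50–500 km² by species range), shuffles non-empty blocks, and deals
them round-robin to 5 folds so co-located rows always share a fold.
The overfitting check passes when train AUC exceeds neither CV mean by
0.1 or more (strict <). Individuals are pooled within species: a tree
ensemble carries no random effect, and mixed-model comparison arms are
out of scope. With a fixed seed the fit→predict path is bit-reproducible.

## Projection and scenarios

Suitability is the model's predicted occurrence probability per grid
cell. Zone statistics use cell-centre containment and the inclusive
threshold ≥ 0.67 for "highly suitable habitat" (the inclusive reading is
applied once, everywhere). Scenario deltas score the same historical
model on historical and shifted stacks and difference cellwise, per
month, then annual-mean; the operation is exactly antisymmetric in its
stack arguments and exactly zero for identical stacks. Percent change in
highly suitable habitat is per species (then averaged with SD across
species, matching the mean ± SD reporting style); a zero historical
baseline is reported as undefined rather than a percent.

## Synthetic world

The generator is the package's study-conditions module, not a test prop:

- **Grid**: 20°×20° at 0.25° around a Palmyra-like atoll (colony at
  −162.076°, 5.882°), 12 monthly layers; MPA = ±1.9° box around the
  colony inside a ±6° EEZ box, mimicking 50 nm / 200 nm zoning.
- **Fields**: per covariate, a persistent low-frequency sinusoid pattern
  plus month-specific smoothed-noise anomalies (and a seasonal SST
  cycle), scaled to realistic tropical ranges (SST ≈ 28 ± 1.5 °C,
  chl ≈ 0.12 mg m⁻³, DO ≈ 200 mmol m⁻³, currents ≈ ±0.25 m s⁻¹);
  bathymetry is a −4500 m basin with a smooth seamount rising to a −20 m
  atoll cell. Adjacent-cell differences are reliably smaller than random
  pairs, which is all downstream spatial methods require.
- **Movement**: a biased correlated random walk — 16 candidate headings
  scored by cos(turn) persistence plus the preference-weighted
  standardized covariate field, sampled by softmax; step lengths are
  Beta(2,2)-scaled below vmax·Δt, so speed limits hold by construction.
  Preferences are linear per covariate, or hump-shaped
  (−coef·(z − optimum)²) for species with a declared optimum — the
  construct that lets warming-past-optimum experiments have a known sign.
  Central-place species alternate outbound trips (~6–36 h) with
  colony-attracted returns; nearshore guilds carry a hard range cap,
  which is what makes the "100% inside MPA" fixture exact rather than
  probabilistic.
- **The nine-species design** spans the study's structure: sample rates
  2 min–12 h, deployments 0.5–350 days, three guilds, seabird trip
  structure, optional gap injection. The three-species demo (dolphin /
  reef shark / tuna) is sized to run the full pipeline in minutes:
  at 12 monthly layers it yields roughly 90–1000 daily presences per
  species and 400–2000 model rows.
- **Scenarios**: future stacks are the historical fields with additive or
  multiplicative shifts (default: +1.0 °C with DO −4 mmol m⁻³, and
  +2.5 °C with 10% chlorophyll loss and DO −10 mmol m⁻³); bathymetry
  never changes.

What passing tests show — and what they do not: the generator has smooth
fields, exact speed bounds, independent step/turn marginals, and
noise-free positions. Real tags bring Argos error ellipses, light-level
geolocation uncertainty, battery failure, and covariate products with
their own error structure; none of these are emulated beyond simple gap
injection, so the tests certify the *methods* (filters, estimators,
cross-validation, differencing), not field-data error handling.

## Numerical and I/O choices

Randomness flows through explicitly passed seeded generators; there is no
global state, and a config seed fully determines all outputs. Tracks and
tables are CSV; polygons are GeoJSON (WGS84) via shapely; gridded stacks
and rasters are CF-style NetCDF (lon/lat/time) written through xarray.
Cross-validation experiments that probe the evaluation machinery (block
vs. random folds; scenario sign recovery) use lighter boosting settings
than the production hyperparameters — those experiments test fold
construction and differencing logic, for which 2000-tree ensembles add
runtime but no information.

## Known limitations

- The speed filter is a generic iterative great-circle filter, not a
  distance-angle-rate filter; hidden-Markov geolocation post-processing
  of archival tags is out of scope (tracks are taken as decoded).
- Mixed-model (GLMM/GAMM) comparison arms and dive-depth mixed models are
  not implemented; the evaluation harness accepts any scorer if such arms
  are added.
- Spatial blocks are squares in the projected plane; no buffered or
  environmental blocking.
- The land mask is bathymetry-sign based and off by default.
- Isopleth polygons are unions of grid cells, not smoothed contours, so
  their boundaries are resolution-dependent (areas converge with the
  150-interval grid).
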