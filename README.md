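# mpatrack

Multi-species animal telemetry, space-use estimation, and climate-scenario
habitat modelling for assessing how well a large-scale marine protected
area (MPA) protects highly mobile species.

Remote tropical MPAs are drawn around atolls and reefs, but the seabirds,
cetaceans, pelagic fishes, manta rays, and reef sharks that use them range
far beyond any fixed boundary. `mpatrack` implements, as a tested and
reusable pipeline, the analysis chain that turns raw multi-tag tracking
data into protection accounting and forward-looking habitat projections:

1. **Track processing** — deployment trimming, species-specific
   great-circle speed filtering, colony-point removal and central-place
   foraging-trip segmentation for breeding seabirds, time-regularization
   by vmax-gated great-circle interpolation, and reduction to one
   *geodesic median* location per individual per local (HST) day — the
   common currency across tags sampling from 2 min to 12 h.
2. **Space use** — bivariate-normal kernel utilization distributions (UDs)
   with the reference bandwidth h_ref = ½(σ_x + σ_y)·n^(−1/6), fitted
   separately to daily locations inside and outside the MPA; 50% ("core")
   and 95% ("general") isopleth areas in km²; multi-species overlap counts
   on 10/50 km management grids.
3. **Habitat models** — presence vs. pseudo-absence species distribution
   models. Pseudo-absences come from uniform *background* sampling within
   each individual's track extent or from *correlated random walks* (CRW)
   that resample the observed step-length and turning-angle distributions
   (100 simulations per individual, 1:1 presence:absence). Models are
   boosted regression trees (bernoulli loss; learning rate 0.005, tree
   complexity 5, 2000 trees, bag fraction 0.75) on standardized
   environmental covariates (SST, chlorophyll-a, dissolved oxygen, current
   u/v plus derived speed √(u²+v²) and heading atan2(v,u), bathymetry),
   evaluated with training AUC, 10-fold cross-validated AUC/TSS, 5-fold
   *spatial block* cross-validation, deviance-explained R², Bhattacharyya
   environmental-dissimilarity coefficients, and an overfitting check
   (train−CV AUC gap < 0.1).
4. **Projection** — per-cell habitat suitability over the study grid,
   zone summaries with the ≥ 0.67 "highly suitable" threshold, multi-species
   means and counts, and climate-scenario deltas: the historically trained
   model scores monthly-median composite fields for future decades and the
   future-minus-historical difference maps habitat gain/loss.

Because the deposited tracking data cannot ship with the code, a
first-class **synthetic data generator** reproduces the study's structure
(nine species in nearshore-pelagic / reef-pelagic / pelagic guilds,
central-place seabird trips, data gaps, known covariate-driven occurrence
preferences) so every stage is testable end to end with recoverable
ground truth.

## Worked example

```python
import numpy as np
from mpatrack import synthetic_data as sd, track_processing as tp

# a small synthetic study: 20x20 deg tropical grid, 3 monthly layers
world = sd.fixture_world(seed=7, months=3)
dolphin = world.species[0]                      # nearshore-pelagic guild
tracks = sd.simulate_tracks(world, dolphin, seed=7)

fracs = []
for raw in tracks:
    clean = tp.speed_filter(raw, dolphin.vmax)
    daily = tp.daily_geodesic_median(clean)
    fracs.append(tp.percent_inside(daily, world.zones["mpa"]))
print(f"{dolphin.name}: {len(tracks)} individuals, "
      f"{100 * np.mean(fracs):.1f}% of daily locations inside the MPA")

from mpatrack import sdm
from mpatrack.env_covariates import ALL_COVARIATES, standardize
from mpatrack.pipeline import build_presence_table

tuna = world.species[2]                         # pelagic, warm-water preference
dailies = [tp.flag_zones(tp.daily_geodesic_median(tp.speed_filter(t, tuna.vmax)),
                         world.zones)
           for t in sd.simulate_tracks(world, tuna, seed=7)]
table = build_presence_table(dailies, world, seed=8)
table, scaling = standardize(table, covariates=ALL_COVARIATES)
covariates = [c for c in ALL_COVARIATES if c in table]
model = sdm.fit_brt(table, covariates, {"n_trees": 500}, seed=7,
                    species=tuna.name, scaling=scaling)
cv = sdm.cv_kfold(table, covariates, k=10, hyperparams={"n_trees": 500}, seed=7)
print(f"{tuna.name}: n={len(table)} presence/absence rows, "
      f"10-fold CV AUC = {cv['auc_cv_mean']:.3f}")
print("top covariates (% relative influence):")
print(model.relative_influence.head(3).round(1).to_string())
```

prints

```
bottlenose dolphin: 5 individuals, 100.0% of daily locations inside the MPA
yellowfin tuna: n=1542 presence/absence rows, 10-fold CV AUC = 0.899
top covariates (% relative influence):
sst    63.4
do     10.1
chl     6.1
```

The confined nearshore species is fully contained by the MPA box; the
wide-ranging tuna is generated with a warm-water preference (coefficient 2
on standardized SST), and the fitted model both discriminates well
(CV AUC 0.90) and correctly ranks SST as the dominant covariate.

A command-line interface wraps the same stages:

```bash
mpatrack demo --out demo_world --seed 2      # fixture tracks/zones/stacks
mpatrack run  --out demo_run   --seed 2      # full pipeline -> results.json
```

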