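# oroinvade

Analysis pipeline for alien vertebrate distributions in mountains:

- **synthworld** — synthetic world generator (realms, disjoint mountain
  polygons with a system ⊂ region ⊂ continent hierarchy, DEM with
  class-forcing elevation distributions, predictor rasters, monthly climate
  stack, species with polygonal native ranges, occurrence records with known
  native/alien truth labels, protected areas) for fully offline end-to-end
  testing with exact ground truth.
- **ingest_filter** — point-in-polygon mountain assignment, the spatially
  explicit native-range alien filter, per-mountain richness / record-density
  tables, sampling-completeness residuals.
- **realm_flows** — donor→recipient realm flow matrices (multi-realm natives
  count once per donor; intra-realm flows legitimate) and a resampling null
  test (draws without replacement from the global native pool; verdicts from
  the empirical 2.5% / 97.5% order statistics of 999 draws).
- **protected_areas** — status/IUCN-category filtering (WDPA dialect
  accepted), record–PA overlap, per-category and per-realm×category
  summaries with mountain-portion area correction on an equal-area
  projection.
- **mountain_metrics** — 3×3 max−min terrain roughness, four-class mountain
  geometry (moment skewness + Hartigan's dip test with Monte-Carlo p-values;
  hourglass overrides skewness), gradient-based climate velocity
  (trend of annual means / latitude-corrected spatial gradient), zonal means
  and great-circle minimum distances.
- **invasion_glmm** — negative-binomial (NB2) mixed models with nested
  random intercepts and a log-area offset, fitted by an in-package Laplace
  engine; collinearity screening at |r| > 0.7, standardization to mean 0 /
  SD 1, diamond geometry baseline, Wald statistics, taxon-specific models
  and sensitivity refits.
- **pipeline_cli** — YAML-configured orchestration with deterministic
  seeding, a run manifest and JSON-lines logs.

## CLI

```sh
oroinvade synth --out world/ --seed 1            # generate a synthetic world
oroinvade filter --records world/occurrences.csv \
    --mountains world/mountains.geojson --ranges world/ranges.geojson --out out/
oroinvade flows --records out/records_kept.csv --ranges world/ranges.geojson \
    --realms world/realms.geojson --draws 999 --seed 42 --out out/
oroinvade pa --records out/records_kept.csv --pas world/pas.geojson \
    --mountains world/mountains.geojson --out out/
oroinvade predictors --mountains world/mountains.geojson --dem world/dem.asc \
    --climate world/climate_tmin.nc --rasters bii=world/bii.asc --out out/
oroinvade fit --data joined.csv --scope all --out out/
oroinvade run --config run.yaml                  # full pipeline
oroinvade validate --layer records=occ.csv       # schema/geometry checks
```

A minimal `run.yaml`:

```yaml
out_dir: runs/demo
seed: 1
world: {n_mountains: 40, n_species_pool: 150}
thresholds: {n_draws: 999}   # dip 0.01, p 0.05, skew 0.5, |r| 0.7 are defaults
```

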