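# paleopeace

A tested, reusable pipeline linking Holocene climate reconstructions,
radiocarbon-based relative population density, and socio-political
complexity to the probability that an individual shows no craniofacial
trauma ("probability of peaceful interactions", PPI). The chain runs
from calibration of 14C dates and composite-KDE population proxies,
through per-individual Monte-Carlo exposure sampling, to iterated
probability-forest ensembles with permutation importance and partial
dependence, aggregated into summary bands, PPI ranges and correlation
matrices. A synthetic-world generator with a known logistic trauma
model provides recoverable ground truth for every stage.

## Layout

- `paleopeace.synthetic` — synthetic study world (grids, ocean cores,
  dates, individuals) with known generative parameters
- `paleopeace.radiocarbon` — `.14c` curve parsing, calibration, error
  filtering, 200-yr same-site binning, 1000-replicate composite KDEs,
  taphonomic correction
- `paleopeace.exposures` — coast/inland classification, 20-km buffer
  means, per-individual draws of climate, SST, ENSO and population
  density
- `paleopeace.forest` — collinearity screening, per-site subsampling,
  stratified splits, probability forests, AUC/MSE/log-loss metrics,
  permutation importance, 1D/2D partial dependence, ensemble driver
- `paleopeace.reporting` — run aggregation (means, 2 SD bands, 95% CIs),
  PPI ranges, correlation matrices, CSV/JSON writers
- `paleopeace.config` / `paleopeace.pipeline` / `paleopeace.cli` —
  TOML configuration, orchestration, command line

## CLI

```sh
# full synthetic run: simulate -> calibrate/CKDE -> exposures -> ensembles -> reports
paleopeace all --config run.toml --seed 7 --out-dir out/

# individual stages
paleopeace simulate --seed 3 --out-dir out/
paleopeace calibrate out/data/dates.csv --out calibrated.csv
paleopeace summarize out/data/individuals.csv
```

A minimal `run.toml`:

```toml
seed = 7
n_draws = 1000

[world]
n_sites = 30
n_individuals = 1000
n_dates = 400

[model]
n_models = 100
n_trees = 100
```

Outputs land in the configured directory: `summary_<region>.json`,
`importance_<region>.csv`, `pd_curves_<region>.csv`,
`pd_surfaces_<region>.csv`, `ppi_ranges_<region>.csv`,
`correlation_<region>.csv`, per-run `metrics_<region>.csv`,
`population_kdes.csv`, `dataset_summary.json` and a `manifest.json`
with the config hash and stage timings. Exit codes: 0 success,
2 validation error, 3 data/stage error.

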