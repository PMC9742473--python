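# cornbelt

County-scale maize yield prediction for Corn-Belt-style panels: a synthetic
data generator emulating the public data stack (county yields, weekly
weather, layered soil, state planting progress, crop-simulation outputs),
crop-model-augmented feature engineering, two-stage feature selection, five
base learners with Bayesian hyperparameter search, and a constrained
optimized-weight ensemble, evaluated year-ahead with regional error
analysis.

## What it does

1. **`cornbelt.synth`** generates a county × year panel with a configurable
   state → crop-reporting-district → county hierarchy: 293 weekly weather
   feature columns, 100 soil columns (10 properties × 10 depths), 52 weekly
   cumulative planting-progress columns per state-year, the 37-variable
   crop-simulation output block whose `AnnualYield` correlates with the true
   yield at a configurable fidelity, a linear per-county yield trend, and
   structured missingness (pre-cutoff planting gaps for one state, random
   crop-model gaps). An optional windstorm-style shock hits a configurable
   county subset in one year.
2. **`cornbelt.preprocess`** left-joins everything onto the yield reference,
   imputes planting gaps with state week means and crop-model gaps with
   county medians, adds 20 quarterly weather aggregates, and fits the
   per-county yield-on-year trend feature on training years only.
3. **`cornbelt.selection`** drops weekly weather outside weeks 16–43 and
   planting outside weeks 12–29, then ranks the survivors by permutation
   importance (validation-MSE increase) under a random forest and keeps the
   top 100.
4. **`cornbelt.learners`** fits linear, L1-linear, random-forest, and two
   gradient-boosting regressors under a strict year-ahead split, tuned by a
   Gaussian-process Bayesian search (40 evaluations, 10-fold CV by default),
   and assembles out-of-fold prediction matrices for stacking.
5. **`cornbelt.ensemble`** fits equal weights and the optimized weights:
   minimize training root-mean-square error over the weight simplex subject
   to the ensemble dominating every base learner's training MSE. An
   exhaustive simplex-grid oracle verifies the solver.
6. **`cornbelt.evaluation`** computes RMSE / RRMSE(%) / MBE / R², applies the
   shock-county exclusion to the evaluation set only, aggregates errors by
   county/CRD/state with cropland ratio, and screens county RMSE against
   soil/weather covariates with Pearson correlations.
7. **`cornbelt.pipeline`** chains everything per test year under one root
   seed, including a paired with/without-crop-model comparison.

## CLI

```bash
cornbelt simulate --out data/                      # six CSV tables
cornbelt preprocess --data data/ --out features/
cornbelt select --features features/ --data data/ --test-year 2020 --out sel/
cornbelt train --features features/ --selected sel/selected_features.json \
    --data data/ --test-year 2020 --out preds/
cornbelt ensemble --predictions preds/ --out ens/
cornbelt evaluate --predictions ens/ensemble_predictions.csv --data data/ \
    --out metrics.csv
cornbelt analyze-errors --predictions ens/ensemble_predictions.csv \
    --features features/ --data data/ --out errors/
cornbelt run-all --out run/                        # everything per test year
cornbelt compare-apsim --out compare.csv           # paired ablation
```

Scenario parameters live in a YAML file mirroring
`cornbelt.synth.ScenarioConfig` (pass `--config scenario.yaml`). Defaults:
12 states × 2 CRDs × 3 counties, 1984–2020, shock year 2020 with 27 shocked
counties.

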