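# coxmiss

A resampling benchmark for missing-covariate methods in Cox proportional
hazards modelling.

The package generates a synthetic complete survival population calibrated to
a large colorectal-cancer trial cohort (one left-skewed continuous covariate,
seven binaries with fixed marginals and strong pairwise associations, 35%
events, 64% five-year survival, median censored follow-up 6.5 years), imposes
multivariate missing-at-random missingness on three covariates according to a
seven-pattern table, applies five missing-data methods, fits the 8-covariate
Cox model to every completed dataset, pools multiply-imputed results by
Rubin's rules, and evaluates bias, coverage, efficiency and prognostic
performance (Nagelkerke R², the rank-based prognostic-separation D statistic,
predicted 2/5-year survival) against complete-data reference values.

## Methods

| Label    | Method |
|----------|--------|
| CC       | Complete-case analysis |
| SI       | Single imputation: regression switching with predictive mean matching |
| MICE     | Multiple imputation: chained equations with parametric draws |
| MICE-PMM | Multiple imputation: chained equations with predictive mean matching |
| AREG-PMM | Multiple imputation: additive (restricted-cubic-spline) models, bootstrap parameter uncertainty, PMM |

All five engines, the Cox fitter (Newton-Raphson with Efron ties), the
amputation mechanism and the pooling rules are implemented in this package;
`lifelines` is used only as an independent reference in the test suite.

## Layout

- `coxmiss.population` — synthetic population: skew-normal age, Gaussian-copula
  binaries calibrated to target phi coefficients, Weibull proportional-hazards
  event times, scaled-Beta administrative censoring, bootstrap sampling,
  Kaplan-Meier utilities.
- `coxmiss.amputation` — pattern table, MAR score, exact-count weighted
  amputation, missingness summaries.
- `coxmiss.impute` — the five engines plus the PMM and spline primitives.
- `coxmiss.survival` — Cox fit, Nagelkerke R², prognostic separation D,
  Breslow baseline and predicted survival.
- `coxmiss.pooling` — Rubin's rules, performance-measure pooling, estimator
  evaluation, replication-accuracy calculator.
- `coxmiss.harness` — factorial study orchestration with per-replication
  deterministic seed streams.
- `coxmiss.cli` — command-line interface.

## CLI

```sh
coxmiss generate-population -n 7507 --seed 1 -o pop.csv
coxmiss ampute -i pop.csv --p0 0.25 --seed 2 -o incomplete.csv
coxmiss impute -i incomplete.csv --engine MICE-PMM -m 10 --seed 3 -o imp
coxmiss fit -i imp.0.csv
coxmiss run-truth --scaled -o truth.json
coxmiss run-study --scaled -o report/
```

Datasets are plain comma-separated text (blank fields mark missing entries);
configs are YAML; study reports are tab-separated tables.

## Defaults worth knowing

- 10 imputations, 5 chained-equation cycles, donor pool of 3 for PMM; all
  configurable via `ImputationConfig`.
- Imputation models use all other covariates, the event indicator and
  log survival time (a Nelson-Aalen cumulative-hazard predictor is available
  behind a flag).
- The generating log hazard ratios and the amputation score weights are
  calibrated surrogates (the source cohort's fitted model is not published);
  both are plain config fields.
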