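# scentselect

A tested, reusable pipeline for analysing plastic responses of floral
volatile emissions (and other floral traits) to snowmelt-timing and
precipitation manipulations, and for estimating how natural selection on
those traits shifts with the environment.

The package covers the full chain from raw GC-MS peak tables to
adaptive-plasticity classification:

| Stage | Module | What it does |
| --- | --- | --- |
| Simulation | `scentselect.synthetic` | Split-plot field studies (6 whole plots x 4 subplots x 3 years) with correlated lognormal emissions, soil-moisture structure, and fitness components generated from configurable true selection gradients |
| Quantitation | `scentselect.volatiles` | Four-rule compound filtering (retention-time window, occurrence, 4x ambient ratio, contaminant list) with an audit trail; through-origin calibration; emission rates (ng flower⁻¹ h⁻¹); plant averaging; sqrt transform; compound-class totals |
| Ordination | `scentselect.ordination` | Bray–Curtis distances, principal coordinates (negative eigenvalues discarded and counted), constrained ordination with sequential per-term inertia, free-permutation tests, percent inertia |
| Mixed models | `scentselect.lmm` | REML split-plot models (plot and subplot-in-plot random intercepts), estimated marginal means, Cohen's d plasticity effect sizes, plasticity correlations |
| Fitness | `scentselect.fitness` | Four female-fitness measures (total seeds with dehisced/early-collection imputation, seeds initiated per flower, escape from seed predation, fly eggs per flower), relativized by the pooled grand mean |
| Selection | `scentselect.selection` | Compound-class selection models with treatment interactions; univariate trait x environment models with the interaction drop rule; elastic-net direct gradients (mixing 0.5, CV-chosen penalty, environment covariates unpenalized) |
| Concordance | `scentselect.concordance` | Plasticity fold changes (EMM ratios) x new-environment selection; adaptive/maladaptive/neutral quadrant classification; exact binomial proportion tests; stringent-significance cross-tabs |
| Orchestration | `scentselect.cli` | `scentselect` CLI, config-hashed caching, run manifests, input validation |

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the statistical acceptance criteria
(ordination oracle equivalence, permutation-test calibration at 500 null
replicates, selection-gradient and interaction-slope recovery, filter and
fitness arithmetic exactness, concordance truth table). The full suite
runs in a few minutes on one CPU.

## CLI

Run the complete pipeline on a synthetic study:

```sh
scentselect run --seed 1 --outdir out/
```

which writes the simulated inputs, the emission matrix and class totals,
CAP term tests, mixed-model coefficients, the fitness table, selection
gradients, concordance records, and a `manifest.json` (config hash,
per-stage row counts, warnings, timing). Individual stages are exposed as
subcommands with file inputs:

```sh
scentselect simulate  --seed 1 --outdir study/
scentselect volatiles --peaks study/peak_table.csv --dilution study/dilution_series.csv \
                      --outdir out/ --rt-min 2 --rt-max 17 --min-freq 0.10 --ambient-ratio 4
scentselect cap       --matrix out/emission_matrix.csv --design study/trait_table.csv \
                      --terms "year,precip_treatment,snow_treatment" --outdir out/
scentselect fitness   --components study/fitness_components.csv --outdir out/
scentselect selection --traits study/trait_table.csv --fitness out/fitness_table.csv --outdir out/
scentselect concordance --traits study/trait_table.csv --fitness out/fitness_table.csv --outdir out/
scentselect validate  --components study/fitness_components.csv --peaks study/peak_table.csv
```

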