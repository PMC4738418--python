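# valsize

Resampling machinery for studying **sample-size requirements when externally
validating time-to-event prognostic models**. Given a large survival cohort
and a fixed prognostic model, `valsize` draws stratified with-replacement
samples with a fixed number of outcome events, computes six validation
performance measures on every replicate, and summarizes how bias, precision
and confidence-interval coverage of those measures depend on the number of
events.

Because suitable licensed registry data cannot be redistributed, the package
ships a synthetic cohort generator with known ground truth: correlated
(optionally skewed) covariates drive a Weibull proportional-hazards outcome
with exponential dropout and administrative censoring, and the "published
model" under validation can be deliberately miscalibrated (shrunken or
inflated coefficients, perturbation noise).

## Components

| module                | what it does |
|-----------------------|--------------|
| `valsize.cohort`      | synthetic populations, event-rate calibration by bisection, miscalibrated validation models, true performance values |
| `valsize.measures`    | Harrell c-index (Noether-type SE), D statistic via scaled normal order scores, R²_D transform, explained randomness ρ²_OXS, IPCW Brier score, calibration slope and curve; single-covariate Cox fit (Efron ties) and censoring Kaplan-Meier primitives |
| `valsize.resampling`  | fixed-event-count stratified resampling, counter-based seeding, replicate streaming, model-based vs empirical vs bootstrap SE sub-study |
| `valsize.evaluation`  | percent/standardized bias, RMSE, coverage with acceptable Monte-Carlo band, mean CI width, within-tolerance proportions, long-format summary tables |
| `valsize.cli`         | `valsize simulate | run | evaluate | all` |

## Command-line usage

Configuration is a flat `key = value` file; a seed is mandatory.

```bash
cat > run.cfg <<EOF
n = 200000
event_fraction = 0.054
events = 10, 25, 50, 100, 200, 500
replicates = 2000
seed = 42
EOF

valsize all --config run.cfg --out results/
```

This writes `population.csv` (columns `id,time,event,pi,risk10`),
`theta.json` (true measure values on the full population), one
`scenario_<events>.csv` of replicate-level estimates per event count,
`summary.csv` (one row per measure × event count with bias, RMSE, coverage,
CI width and within-tolerance proportions), and a manifest per step with the
config echo, seed and package versions. Identical config + seed reproduce
byte-identical outputs. `--paper-scale` switches to the full design (event
grid 5…1000, 10 000 replicates, 200 bootstrap replications) — expect hours,
not minutes.

Steps can also be run separately (`simulate`, `run`, `evaluate`), and
`run --population my_cohort.csv` accepts any user-supplied cohort CSV with
the columns above.

## Python API sketch

```python
from valsize import cohort, resampling, evaluation

spec  = cohort.default_covariate_spec()
truth = cohort.TrueDataModel(beta_true=cohort.beta_for_pi_sd(spec, 0.95))
truth = cohort.calibrate_event_rate(spec, truth, 200_000, seed=42)
pop   = cohort.generate_population(spec, truth, 200_000, seed=42)
theta = cohort.true_performance(pop).theta_dict()

specs   = resampling.make_grid([10, 25, 50, 100, 200, 500], 2000, master_seed=7)
results = resampling.run_grid(pop, specs)
summary = evaluation.summarize(results, theta)
```

## Notes on conventions

- Higher prognostic index ⇒ higher risk; informative models score c > 0.5.
- Cox ties use the Efron correction.
- The censoring Kaplan-Meier is evaluated at `t−` in the first Brier term
  (switchable via `left_limit=False`).
- The calibration curve is a natural-spline Cox fit on `cloglog(risk)` — a
  documented stand-in for adaptive hazard regression — with a decile
  Kaplan-Meier fallback (logged) when the fit is degenerate.
- Confidence intervals are Wald on the natural scale throughout.
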