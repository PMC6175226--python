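# ipdmetasim

A simulation framework for comparing **one-stage** and **two-stage**
individual patient data (IPD) meta-analysis of a continuous outcome.

The package generates multi-study patient-level datasets with a binary
exposure, one covariate (continuous or binary), an optional
exposure-by-covariate interaction, and between-study heterogeneity injected
through random effects scaled to target I² levels.  It then analyses each
dataset with

- a family of one-stage linear mixed models (`a`, `b`, `c`, `e`, `f`, `g`),
  differing in how the intercept, covariate and interaction enter (common
  fixed, study-specific fixed, or random; the exposure effect is always
  random), estimated by maximum likelihood via `statsmodels.MixedLM`; and
- a two-stage pipeline (`d`): per-study OLS followed by inverse-variance
  random-effects pooling with both the DerSimonian–Laird moment estimator
  and a REML estimator of the between-study variance τ².

A Monte-Carlo harness runs the full factorial design — 8 simulation
settings × 9 study-size configurations × 6 (intercept, exposure) I² pairs —
with splittable seeding and reports **mean bias**, **mean error**,
**coverage**, **power** and **convergence rate** per model.

## Layout

| module | contents |
|---|---|
| `ipdmetasim.simulate` | `ScenarioSpec`, setting presets 1–8, random-effect generators (normal and cubic-of-normal skewed), `generate_ipd` |
| `ipdmetasim.select` | small-study-effect filter (publication-bias proxy, setting 2) |
| `ipdmetasim.onestage` | one-stage model registry and `fit_onestage` |
| `ipdmetasim.twostage` | `first_stage`, `pool_DL`, `pool_REML`, `pool_fixed` |
| `ipdmetasim.metrics` | performance measures and `MetricsSummary` |
| `ipdmetasim.harness` | `GridSpec`, `run_cell`, `run_grid` |
| `ipdmetasim.cli` | `ipdmetasim` command-line entry point |

## Command line

```sh
# one dataset (CSV + JSON sidecar with the true parameters)
ipdmetasim simulate --setting 1 -k 10 --mean-size 500 --seed 1 -o data/ds.csv

# one grid cell: 200 iterations, models a-d
ipdmetasim run-cell --setting 1 --total-n 2000 -k 8 --mean-size 250 \
    --i2-intercept 0.5 -n 200 --seed 1 -o out/cell

# a configured grid (see configs/table1_grid.yml)
ipdmetasim run-grid -c configs/table1_grid.yml --settings 1 -n 200 -j 1 -o out/grid

# recompute summaries from a raw per-iteration CSV
ipdmetasim summarize --raw out/cell/raw.csv --truth 0.5 -o out/summary.csv
```

`run-grid` writes `summary.csv` (one row per cell × model, with all five
metrics and the combined (coverage+power)/2 display column), `raw.csv`
(per-iteration fit results) and `convergence.csv`.

## Notes

- Every dataset is reproducible from its `ScenarioSpec` (including the
  seed); grid runs derive per-iteration seeds from the master seed with
  `numpy.random.SeedSequence`, so cells can be executed in parallel
  (`run_grid(..., n_jobs=N)`) without stream overlap.
- Non-converged fits are excluded from bias/error/coverage/power and
  reported through the convergence rate.
- All fitted models see identical datasets within a cell (paired design).
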