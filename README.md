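# pmvalsim

Simulation-based sample-size calculations for **external validation
studies of clinical prediction models** with binary outcomes.

Before a prediction model is used in practice its performance —
discrimination, calibration, clinical utility — should be estimated in
independent data. Rules of thumb ("at least 100 events and 100
non-events") ignore the model and setting, and are often far too small
for calibration. `pmvalsim` instead simulates the planned validation
study and finds the smallest sample size at which every performance
estimate reaches a user-chosen precision (target mean 95% CI width).
It is intended for biostatisticians and applied researchers planning or
justifying the size of an external validation study.

## Model

The model's linear predictor (LP, log-odds scale) in the validation
population is taken as

    LP_i ~ Normal(μ, σ²),        p̂_i = expit(LP_i)

with the *true* outcome risk tied to the LP through a calibration model

    logit(π_i) = γ + S · LP_i,   Y_i ~ Bernoulli(π_i).

`(γ, S) = (0, 1)` is perfect calibration; `S < 1` mimics overfitting;
γ shifts the event rate (it can be solved automatically so that a
desired outcome proportion holds). On each simulated cohort the package
estimates, with 95% CIs:

* **C-statistic** (AUC; DeLong SE),
* **calibration slope** (logistic refit of Y on LP),
* **calibration-in-the-large** (intercept with LP as offset),
* **O/E ratio** (CI on the log scale),
* **integrated calibration index** (lowess calibration curve),
* **net benefit** at a risk threshold p_t,

and aggregates the mean CI width over repetitions. An iterative search
(pilot simulations → `a/√N` width curve → local verification) returns
the minimum N meeting all targets, the implied number of events, the
driving measure, and a full audit trace. See `docs/methods.md` for the
full account.

## Worked example

Validation of a diagnostic model for deep vein thrombosis whose
development-population LP is approximately Normal(−1.75, 1.47²)
(marginal outcome proportion ≈ 0.22, C-statistic ≈ 0.82), assuming the
model is well calibrated, targeting CI widths of 0.1 for the
C-statistic, 0.2 for the calibration slope and 0.2 for ln(O/E):

```python
import pmvalsim as pv

lp = pv.LPDistribution(mu=-1.75, sigma=1.47)
targets = pv.PrecisionTargets(c_statistic=0.1, cal_slope=0.2, oe_log=0.2)
result = pv.find_sample_size(lp, pv.CalibrationParams(), targets, reps=500, seed=42)
```

prints (via `result.per_metric`):

```
overall N = 2442  (~534 events), driven by cal_slope
  c_statistic  N =   385  events =   84.2  achieved width = 0.100 (target 0.1)
  cal_slope    N =  2442  events =  534.0  achieved width = 0.200 (target 0.2)
  oe_log       N =  1373  events =  300.2  achieved width = 0.200 (target 0.2)
```

The calibration slope dominates: ~2450 participants (~530 events) are
needed — far beyond 100-events guidance — while the C-statistic alone
would need only ~385. The returned N wobbles by ~±1–2% across seeds
(Monte-Carlo error of the 500-repetition search).

Expected precision at a *fixed* sample size (here N = 461, an average
of ~100 events per cohort):

```python
spec = pv.ScenarioSpec(lp=lp, n=461, seed=42)
summary = pv.run_precision(
    spec, ("c_statistic", "cal_slope", "oe_ratio", "net_benefit"), reps=1000
)
print(summary.to_frame().round(3))
```

```
     metric  mean_estimate  mean_ci_width  mean_log_ci_width  n_converged  reps
c_statistic          0.815          0.092                NaN         1000  1000
  cal_slope          1.010          0.463                NaN         1000  1000
   oe_ratio          1.001          0.347              0.346         1000  1000
net_benefit          0.154          0.078                NaN         1000  1000
```

With ~100 events the C-statistic is already precise (width 0.09) but
the calibration slope is not (width 0.46) — the usual reason validation
studies need to be larger than rules of thumb suggest.

The same workflows are available from the shell:

```bash
pmvalsim find-size --config dvt.cfg --out results/
pmvalsim assess-precision --config dvt.cfg --n 461
pmvalsim grid --config grid.cfg
```

where `dvt.cfg` is a flat key=value file (keys documented in
`pmvalsim/config.py`), e.g.

```
lp_mu = -1.75
lp_sigma = 1.47
gamma = 0
slope = 1
targets.c_statistic = 0.1
targets.cal_slope = 0.2
targets.oe_log = 0.2
reps = 500
seed = 42
```

Every run writes a manifest (config + seed + version) sufficient to
reproduce its outputs exactly. Exit codes: 0 success, 1 configuration
error, 2 target unreachable below the sample-size cap.

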