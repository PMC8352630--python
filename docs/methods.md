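# Methods

## The planning problem

After a logistic prediction model is developed, its performance —
discrimination, calibration, clinical utility — should be estimated in
independent (external) data. `pmvalsim` answers the design question for
such a study: *how many participants are needed so that each
performance estimate is precise*, where precision means the width of
its 95% confidence interval. Instead of a rule of thumb (e.g. "100
events and 100 non-events"), the required size is computed by
simulating the planned validation study under an explicit model of the
validation population.

## Data-generating model

Each participant's linear predictor (LP, the log-odds score produced by
the model) is drawn

    LP_i ~ Normal(mu, sigma^2)

and the model's prediction is `p_i = expit(LP_i)`. The *true* outcome
risk is linked to the LP through the calibration model

    logit(pi_i) = gamma + S * LP_i,        Y_i ~ Bernoulli(pi_i)

so `(gamma, S) = (0, 1)` means the model is perfectly calibrated in the
validation population; `S < 1` mimics overfitting (predictions too
extreme); `gamma` shifts the overall event rate. A *miscalibration
factor* `m` is the special case `(gamma, S) = (0, m)`: outcomes are
generated from `m * LP` while predictions still use `LP`.

`expit(mu)` is the **base probability** — the risk of an individual at
the mean LP. It equals the event proportion only when `sigma = 0`; in
general the marginal event proportion is

    pi = E[ expit(gamma + S * LP) ],   LP ~ N(mu, sigma^2),

which `expected_event_proportion` evaluates by Gauss–Hermite quadrature
(150 nodes; agreement with adaptive quadrature is ~1e-10 for the sigma
range of interest, far below the 1e-6 contract). Because the integral
is deterministic, `solve_gamma` can invert it exactly: given a desired
event proportion and an assumed slope, a bracketed Brent root-find
returns the `gamma` that achieves it (closed form when `sigma = 0`).
The expectation is strictly increasing in `gamma`, so the root is
unique; failure to bracket raises rather than clamping.

Scenario inputs that are usually published — a base probability and a
C-statistic rather than `mu` and `sigma` — are supported:
`sigma_from_target_c` inverts the population C-statistic (computed with
common random numbers so the inversion is smooth and deterministic) to
recover `sigma`.

### Events-to-N conversion

A scenario may be specified by the expected number of events `E`
instead of N. Two conversions are exposed:

* `base_probability` (default): `N = ceil(E / expit(mu))` — the
  convention used to define factorial planning scenarios. With
  `sigma > 0` the realised mean event count then *exceeds* E, because
  the marginal event proportion exceeds the base probability for
  left-skewed risk distributions.
* `event_proportion`: `N = ceil(E / pi)` with `pi` from the quadrature
  above — the realised mean event count matches E. The worked
  DVT example below corresponds to this convention.

Rounding is always up, so the expected event count is at least E.

## Performance measures

Estimated per simulated cohort (`metrics` module); every CI is
`estimate ± 1.96·SE` on the original scale except O/E:

* **C-statistic** — concordance probability with ties counted 1/2
  (identical to the area under the ROC curve), computed by midranks in
  O(N log N). The SE is the DeLong covariance estimator, cross-checked
  in the test suite against the pROC reference implementation. The CI
  is stored untruncated so the width identity holds exactly; display
  layers may clip to [0, 1].
* **Calibration slope** — ML logistic regression of Y on (intercept,
  LP); the LP coefficient with its Wald SE.
* **Calibration-in-the-large** — ML logistic fit of Y on an intercept
  with the LP as a fixed offset (slope held at 1).
* **O/E ratio** — mean observed outcome over mean predicted
  probability; `se(ln O/E) = sqrt((1-O)/(N·O))`, the binomial
  approximation that treats the expected value as fixed; the CI is
  built on the log scale and back-transformed.
* **ICI** — mean absolute difference between a locally weighted
  (lowess) calibration curve of Y on p-hat and the 45-degree line,
  span 0.75, local-linear without robustifying iterations (robust
  reweighting treats the events at low predicted risk as outliers and
  flattens the curve for binary responses). SE by nonparametric
  bootstrap (default B = 200); Wald CI by default so the uniform width
  identity holds, percentile CI by option.
* **Net benefit** — at threshold `p_t`, classify positive when
  `p-hat >= p_t` (ties positive);
  `NB = sens·prev − (1−spec)(1−prev)·p_t/(1−p_t)`, computed as the mean
  of per-participant contributions (algebraically identical), which
  yields an analytic SE = SD(contributions)/sqrt(N). This keeps the
  sample-size search free of a nested bootstrap.

**Degenerate inputs.** Cohorts with no events (or no non-events) cannot
support the C-statistic, slope, or O/E; a logistic fit may also fail to
converge or separate at small N. Such repetitions are flagged
`converged = False` — declared when the optimizer fails, or
|coefficient| > 20, or SE > 100 — rather than letting NaNs propagate. A
constant LP makes the slope unidentifiable and raises. The ICI requires
a configurable minimum of 50 participants for the smoother.

## Precision by simulation

`run_precision` simulates `reps` independent cohorts and reports, per
measure: mean estimate, mean 95% CI width (plus the mean ln(O/E) CI
width for O/E), Monte-Carlo SEs of both, and the number of converged
repetitions. Non-converged repetitions are dropped *per metric*, not
per cohort — a separation failure in the slope fit does not discard a
valid C-statistic. The default 500 repetitions keeps the Monte-Carlo SE
of mean widths below ~1% of the width at the scenario sizes used here;
the worked precision tables use 1000.

Per-repetition randomness comes from counter-based seed splitting
(`SeedSequence.spawn`): repetition k's streams depend only on the root
seed and k, so results are bit-reproducible and independent of
execution order, and aggregation is performed in fixed repetition
order. `run_grid` evaluates a factorial of scenarios (defaults:
sigma ∈ {0.2,…,1.0}, base probability ∈ {0.05,…,0.5},
E ∈ {50,…,800}, optional miscalibration factors) with
checkpoint/resume, reporting both expected and mean observed events.

## Sample-size search

`find_sample_size` takes target mean CI widths (any subset of the
measures; the O/E target is set on the ln(O/E) scale, where the
interval is constructed) and finds, per measure, the smallest N in
[start_n, cap_n] whose simulated mean width meets the target; the
overall answer is the maximum, with the driving measure identified and
`events_required = N × pi`.

Mean widths empirically follow `a/sqrt(N)` closely, so the search is:

1. Pilot simulations on a geometric ladder (default 100, 400, 1600).
2. Least-squares fit of `a/sqrt(N)` per measure; propose
   `N* = ceil((a/target)^2)`.
3. Up to three multiplicative corrections `N ← N·(width/target)^2`
   while the measured width is more than 5% from target.
4. A local walk in steps of 1% of N (minimum 1) to the first N whose
   simulated width meets the target.

Every candidate N is evaluated by direct simulation with a seed derived
deterministically from (root seed, N), so the result is an exact
function of (targets, reps, seed) and re-evaluations of the same N
agree; the curve only accelerates the walk. The full evaluation trace
(N, stage, width, MC error) is retained for audit. Monte-Carlo wobble
of the returned N across seeds is on the order of ±1–2% at 500
repetitions. If a target proportion is requested, `gamma` is solved
once up front and the generator is then fixed for the whole search. A
target that is still unmet at `cap_n` (default 10^6) raises
`TargetUnreachableError` carrying the trace.

The "minimum" is defined on *mean* widths; the stricter criterion of
meeting the width in, say, 95% of simulations is out of scope, but the
per-candidate traces retain what such an extension would need.

## Worked scenario (defaults used in tests and the acceptance script)

The bundled examples validate a diagnostic model for deep vein
thrombosis whose development-population LP is approximately
Normal(−1.75, 1.47²), giving a marginal event proportion of 0.2187
(~0.22) and a population C-statistic of ~0.82. Under targets of 0.1 /
0.2 / 0.2 for the C-statistic / calibration slope / ln(O/E) widths, the
slope dominates at roughly N ≈ 2400 (~530 events) — far above
100-events rules of thumb. Assuming miscalibration (S = 0.9 or 0.8 with
`gamma` re-solved to keep the event proportion at 0.22) lowers the
requirement (≈2140 and ≈1900); validating in a shifted population
(LP ~ Normal(−2.67, 1.56²), proportion 0.13) raises it (≈3100). Problem
sizes in the test suite — 500-rep searches, 1000-rep precision tables,
10^6–10^7 draws for population C-statistics — were chosen so
Monte-Carlo error is small relative to the tolerances being checked
while runs stay desk-scale.

## What the generator does and does not emulate

The simulated cohorts capture exactly the features the sample-size
question depends on: the spread of predicted risks, the event rate,
and the true (mis)calibration linking them. They do not emulate
covariate structure, clustering or case-mix heterogeneity beyond the
LP distribution, missing data, or non-normal LP shapes (the `family`
field is an extension point; discrete or skewed LPs from models with
few categorical predictors are not covered). Passing tests therefore
certify the planning machinery under the stated population model, not
the behaviour of any particular dataset.

## Known limitations

* Only binary outcomes; survival extensions would need a censoring
  model and time horizon.
* The normal-LP assumption is load-bearing for the quadrature helpers;
  other families would need their own integration rule.
* The O/E variance formula ignores uncertainty in the expected value;
  at very small event counts the log-scale Wald interval is itself
  approximate.
* The ICI depends on the smoother; a different span (or a spline
  calibration curve) changes its numerical value, so ICI targets should
  be interpreted relative to the span-0.75 lowess used here.
* Head-to-head comparison of competing models is not supported.
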