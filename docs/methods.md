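# Methods

This note records the models, defaults and numerical choices behind
`contingencylab`, and what the simulation-based tests do and do not
establish.

## Schedule model

A session is a planned timeline in seconds from session start.  The `n`
intertrial intervals come from the Fleshler–Hoffman progression: for mean
`m`, the k-th of `n` intervals is

```
t_k = m · [1 + ln n + (n−k) ln(n−k) − (n−k+1) ln(n−k+1)],   0·ln 0 ≡ 0.
```

The sum telescopes, so the analytic mean is exactly `m`; the implementation
renormalizes away floating-point drift (making "mean ITI = 12 minutes" an
exact property, not an approximation) and shuffles the series with the
seed, since the task calls for irregular, not ramped, spacing.  Whether the
original deployment shuffled or ordered its intervals is unknowable from
the outside; shuffling is this package's choice.

Both outcome branches (outcome-if-action, outcome-if-no-action) are
pre-drawn per trial as independent Bernoulli variables.  Because the
branches are independent, this is distributionally identical to drawing at
response time, and it makes a realized session a pure function of
(schedule, behavior).  Judgment probes sit at the end of every 8th trial
with zero dwell time in the plan; response latencies belong to event logs.
Defaults: 40 trials of 6 s (2 s alert-to-button + 3 s response window +
1 s outcome), 120 s miss timeout, 720 s mean ITI — a planned session of
28,800 s of ITI + 240 s of trials ≈ 8.07 h.

## Participant model

Only group labels are simulated, never depression-scale scores.  Behavior
is i.i.d. per trial: a trial is missed with `miss_prob` (default 11.4/40 =
0.285) and an engaged trial receives a press with `press_prob` (default
0.58).  Judgment probes are skipped independently with probability 0.106.
These three defaults are the engagement profile the task produces in
real use; the i.i.d. assumptions are deliberate simplifications (no
time-of-day structure, no fatigue, no missingness mechanism tied to
ratings — i.e. MCAR).

Ratings come from one of two models:

* **Descriptive (default).**  rating = cell mean + participant intercept
  `u ~ N(0, subject_sd²)` + block noise `e ~ N(0, noise_sd²)`, clipped to
  ±100.  The packaged cell-mean table encodes the qualitative pattern of
  interest — low-BDI group mean 14.9 vs high-BDI 1.16, and a +20
  rating-unit density effect under discrete instructions only (none under
  dynamic).  The variance split (subject_sd = 35, noise_sd = 15) was chosen
  once so that the SD of participant mean ratings ≈ 36, which puts
  group-mean standard errors near 5–6 at n = 50–56 and the
  between-participant error mean square near 6,300–6,700 on the
  per-observation scale — the variability regime this task produces.  A
  single i.i.d. per-block noise term cannot hit both quantities at once,
  which is why the random intercept exists.
* **Mechanistic (opt-in).**  rating = 100·(w_action·ΔP_experienced +
  w_density·P(O)_experienced) + noise, clipped.  This implements the
  density-bias account — credit assigned to one's own action grows with
  outcome frequency when the alternative cause is framed as a single
  discrete entity — with `w_density` defaulting higher for low-BDI
  participants and discrete instructions.  It is an explicit modeling
  choice, not an estimated process model, and is off by default.

Because ratings are clipped to the bounded instrument, the population mean
of a cell is the clipped-normal expectation of its configured mean (≈0.6
units below 34.8 for the most extreme default cell); recovery tests
compare against that expectation, not the raw table entry.

## Contingency metrics

ΔP and outcome density are defined over engaged trials only — a missed
trial records neither action nor outcome, so "out of 40" phrasings are not
reproducible from logs.  Conditional probabilities with empty denominators
are reported as explicitly undefined, never coerced to 0; downstream stages
decide how to handle them (the pipeline mean-fills the ΔP covariate and
reports the count).  Per-block covariate windows are cumulative
(session-so-far), matching a judge who integrates all experience to date.

## Imputation

Chained-equation regression imputation: each block column with missing
entries is regressed (OLS) on the other four blocks, 0/1 design-factor
dummies and the centered experienced-ΔP covariate, using rows observed in
that column; missing cells receive the linear prediction plus
`N(0, σ̂²)` residual noise, and the columns are swept 10 times per
imputation so imputed predictors stabilize.  Imputed values are clipped to
±100 (the instrument is bounded by construction); observed cells are never
altered.  Five completed datasets are generated in seed-deterministic
order and the **fifth** is carried into the analysis — a deliberate,
literal implementation of the analyze-one-imputation convention;
`pool_imputations` provides the averaged alternative.

## Inference

The split-plot ANCOVA is fitted in two strata:

* **Between.**  Participant mean ratings on the sum-coded full factorial
  plus the grand-mean-centered covariate; Type-III sums of squares by
  drop-term refits, multiplied by the number of blocks to sit on the
  per-observation scale; error = participants within cells.  Sum-to-zero
  coding keeps the tests invariant to the unbalanced 56/50 split.
* **Within.**  Participant-centered ratings on all terms involving block.
  Centering absorbs the subject effects exactly (every block-term column
  has zero within-subject mean), so this equals the classical
  subject-dummy fit; error df = N(b−1) − rank(block terms).

Error degrees of freedom derive from the design matrix rather than being
fixed constants (with 106 participants, 8 cells and one covariate the
between error df is 97).  Effect sizes: partial η² = SS/(SS+SS_error);
90% limits invert the noncentral-F CDF by bracketed Brent root-finding
(tolerance 1e-8) and map λ to η² via λ/(λ+df1+df2+1); a bound collapses to
0 when the quantile equation has no positive root.  Simple effects test a
factor within each moderator level on participant means against the pooled
error MSE_omnibus / n_blocks with the omnibus between df — the
interpretation under which the omnibus and follow-up error terms differ by
exactly the factor 5.  α = .05 throughout the reporting layer.  Degenerate
inputs: zero-SS effects report F = 0 (also under zero residual error);
zero-variance t tests and non-convergent inversions raise typed errors.

## What the tests show — and do not

Simulation tests run at these scales: 500 sessions per arm for
density/ΔP recovery, 500 null cohorts (complete judgments) for type-I
calibration, 200 full-pipeline replicates (10.6% MCAR missingness +
imputation) for cell-mean recovery, 1,000 random logs for the tabulation
oracle.  They establish that the ANCOVA is well calibrated on complete
data, that the generator hits its programmed probabilities, and that the
imputation chain recovers cell means without bias under MCAR.

Known limitations:

* Analyzing a *single* imputed dataset as if complete is anti-conservative:
  the per-block imputation regressions inject shared structure that
  inflates exactly the within-stratum tests expressible in the imputation
  model (block and block × single-factor terms), while between-stratum
  tests stay calibrated.  Users who care about within-effect test size at
  realistic missingness should pool across imputations instead.
* The generator's MCAR missingness, i.i.d. misses and Gaussian
  compound-symmetric ratings are idealizations; passing tests say nothing
  about informative missingness, serial dependence in engagement, or
  non-normal rating distributions in real deployments.
* The mechanistic judgment model is a parametric stand-in for associative
  accounts, suitable for generating qualitative patterns, not for fitting.
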