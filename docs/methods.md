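# Methods

This document describes the data-generating process, the four development
strategies, the evaluation framework, and the numerical choices behind them.
Default parameter values are package choices made to produce a realistic and
well-conditioned simulation; they are not estimates from any real registry.

## 1. Synthetic cohort generator (`fedcpm.synthetic_cohort`)

### Population structure

The default configuration (`default_config`) mimics a national procedure
registry:

- **16 hospitals** with fixed sizes summing to **16,661 records**, spanning
  roughly two orders of magnitude from the largest (1,850) down to a
  deliberately thin tail of late-starting, low-volume centers (<120 records).
  Each hospital has a start year; records carry a `year` column so the
  low-volume exclusion rule (§5) has something to act on.
- **33 candidate predictors**: 13 standard-normal continuous variables (with
  per-hospital case-mix mean shifts), one threshold-derived binary
  (`bsa_low = 1{bsa < -0.8}`, giving the predictor set one deterministic
  functional dependency), and 19 Bernoulli binaries with center-varying
  rates.
- **Outcome**: Bernoulli with logit-linear true risk
  `logit(p) = beta0 + c_h + x' beta`, where `c_h` is a small per-hospital
  intercept shift. A handful of predictors carry nonzero `beta`; the rest
  are noise. `beta0` is solved numerically (bisection on the analytic
  standard-normal integral, Monte Carlo validated) so that the *weighted mean
  prevalence is 3.4%*, while the center intercepts and case-mix shifts spread
  per-hospital prevalence over approximately **1.2%–5.8%**, non-monotonically
  in hospital size.
- **Missingness**: missing-at-random masks applied per variable with
  configured rates; one variable (`frailty_status`) exceeds the 30% exclusion
  threshold by construction. Missingness probability depends on *observed*
  MAR driver variables (logistic in the drivers), never on the missing value
  itself or the outcome; drivers and the outcome are never masked.

`iid_config` builds a homogeneous variant — no center effects, no case-mix
shifts, no missingness — used by equivalence and recovery tests where the
hospitals must be exchangeable partitions of one population.

Determinism: one `numpy` generator seeded from the config generates hospitals
in label order; `CohortTable.to_csv` round-trips the table plus a JSON schema
of variable kinds.

### Limitations

The generator is logit-linear with independent predictors (aside from the one
threshold variable); it does not model correlated predictors, informative
missingness, temporal drift, or measurement error. Center heterogeneity is
limited to intercept shifts and first-moment case-mix shifts.

## 2. Preprocessing (`fedcpm.preprocess`)

- **Variable filter**: predictors with missingness *strictly above* 30% are
  excluded before modelling.
- **Imputation**: single stochastic imputation by chained equations, run
  either pooled or per-center (`ImputationPlan.scope`). Ten cycles by
  default; targets are visited in increasing order of missing fraction.
  Continuous targets use linear regression followed by **predictive mean
  matching** (donor pool = 5 nearest predictions, vectorized with
  `searchsorted` over the sorted prediction grid), so imputed values are
  always observed values. Binary targets use a ridge-penalized logistic
  model (Newton–IRLS, penalty 1/2·‖w‖² with unpenalized intercept) followed
  by Bernoulli draws. The outcome may be included as a covariate
  (`use_outcome`, the default for model development) or excluded.
  Per-center runs derive each center's seed from `SeedSequence([seed,
  crc32(label)])`, making results invariant to hospital ordering. A
  variable entirely missing within a center is an `ImputationError` under
  per-center scope (nothing to borrow), while pooled scope can proceed.
- **Splits**: stratified k-fold assignment deals events and non-events
  round-robin after a seeded shuffle, guaranteeing fold sizes and event
  counts within one of each other — globally or per center. Leave-center-out
  splits hold out one hospital at a time.

## 3. Model core (`fedcpm.model_core`)

### LASSO logistic regression

`fit_lasso_logistic` minimizes `(1/n)·NLL + lam·Σ|beta_j|` with an
unpenalized intercept, by default on standardized predictors (coefficients
are mapped back to the original scale; selection is decided on the
standardized scale). The solver is IRLS: each outer step builds the weighted
least-squares surrogate (working response `z = lp + (y − mu)/w`, weights
`w = mu(1 − mu)` clipped at 1e-5) and delegates the inner weighted LASSO
subproblem to scikit-learn's coordinate descent (`Lasso` with
`alpha = lam·n/Σw`, which makes the two objectives algebraically identical
under sklearn's sample-weight normalization). `lam = 0` falls back to a
weighted least-squares solve per IRLS step, i.e. plain maximum likelihood.
The outer loop stops when the L1 change in parameters drops below 1e-9, and
breaks early if any coefficient exceeds 35 on the standardized scale —
quasi-separated fits diverge along a fixed direction, and the caller rejects
any fit with |coefficient| > 30 as a `FitFailure` (separation), so iterating
further is wasted work. Verified against `statsmodels` (`lam = 0`) and
scikit-learn's saga solver (`lam > 0`) in the test suite.

`select_lambda` picks the penalty from a grid by inner stratified CV
deviance.

### Recalibration

`fit_recalibration` fits the two-parameter logistic recalibration
`p → expit(a + b·logit(p))` by maximum likelihood — the Cox intercept/slope
method used as a correction rather than a diagnostic. Modes: `central` (one
pair), `local` (one pair per hospital), and `federated`
(`fit_recalibration_federated`, reusing the FedAvg loop on the logit of the
predictions). Since the recalibration map is strictly increasing in `p`
whenever `b > 0`, it never changes discrimination: AUC before and after is
*exactly* equal, which the tests assert as exact equality, not approximate.

## 4. Federation (`fedcpm.federation`)

- **Variable-selection voting**: each center fits its own LASSO and reports
  its selected set; a variable enters the federated model iff the
  size-weighted share of centers selecting it reaches the agreement strength
  `tau` (default 0.5). `tau = 0` gives the union, `tau = 1` the
  intersection.
- **FedAvg**: full-batch gradient descent on the unpenalized logistic loss
  over the voted variables. Each epoch: broadcast parameters, one (or more)
  local gradient steps per center, then a size-weighted parameter average.
  Initialization is zero coefficients with the intercept at the logit of the
  pooled event rate. Centers with a single outcome class are skipped and
  recorded in provenance; if all centers are degenerate the fit fails. With
  one local step per epoch, the update equals pooled full-batch gradient
  descent, so on IID partitions FedAvg converges to the pooled maximum
  likelihood fit (an acceptance property).
- **Ensemble**: per-center LASSO models combined as a size-weighted mean of
  predicted probabilities, with optional recalibration applied after
  averaging.
- **Sharing audit**: the training code records every boundary-crossing event
  (`predictor_data`, `outcome_data`, `model_parameters`, `predictions`) in an
  `AuditTrail`. The executed contracts are: central shares everything;
  local shares nothing; FedAvg shares parameters, predictions, and outcomes
  (for central recalibration) but never predictor records; ensemble shares
  predictions and outcomes but not parameters or predictor records.

## 5. Validation and metrics (`fedcpm.validation`, `fedcpm.metrics`)

- **Cross-validation**: stratified k-fold (k = 10 by default); imputation is
  fitted within each training split and applied to the test split's centers,
  and out-of-fold predictions are stacked so every record is scored exactly
  once. Per-center fit failures (e.g. a zero-event hospital under the local
  strategy) are recorded on the prediction set, never fatal.
- **Leave-center-out**: per held-out hospital metrics, pooled across centers
  by random-effects meta-analysis. The local strategy is rejected here (a
  local model cannot be validated on a center it was never trained on).
- **AUC**: Mann–Whitney rank form with ties counted 1/2 — identical to
  exhaustive pairwise concordance counting. CI by record-level bootstrap.
- **Cox calibration**: ML fit of outcomes on the logit of predicted risk
  with Wald 95% CIs; perfect separation returns a flagged result with
  infinite CIs instead of raising. Miscalibration classification is
  **intercept-first**: `by_intercept` if the intercept CI excludes 0, else
  `by_slope` if the slope CI excludes 1, else `none`.
- **NRI**: category-free (continuous) net reclassification improvement.
- **Paired bootstrap AUC test**: records resampled jointly for both models;
  statistic `D = ΔAUC / sd_boot(ΔAUC)` with a two-sided normal p-value
  (percentile variant available, floored at 1/n_boot). Degenerate resamples
  are redrawn. Its type-I error at the 5% level is checked by simulation.
- **Pooling**: fold metrics are pooled as mean ± 1.96·sd/√k; per-center
  metrics by DerSimonian–Laird random-effects meta-analysis
  (`tau² = max(0, (Q − df)/C)`, inverse-variance weights `1/(se² + tau²)`).

## 6. Study runner (`fedcpm.runner`)

`run_study(StudyConfig)` orchestrates: cohort loading (CSV) or generation,
the ≥30%-missingness filter, both validation designs for all configured
strategies, pairwise NRI and bootstrap-AUC comparisons, sensitivity analyses,
and final-model fits, producing one JSON report plus CSV tables and a
calibration plot.

- **Seeding**: every stage derives its seed from the master seed via
  `SeedSequence([master, crc32(stage_name)])`, so the whole bundle is
  reproducible and stages are independently re-runnable.
- **Sensitivity analyses**: (a) *no recalibration* — identical seeds with
  recalibration disabled; AUCs are exactly equal to the main run (rank
  preservation) while calibration results change; (b) *low-volume
  exclusion* — hospitals with fewer than 10 procedures in any year after
  their first are excluded from training and testing entirely.
- **Final models**: each strategy refitted on the full imputed table;
  per-strategy selected-variable lists and counts are reported, and local
  models that cannot be fitted (e.g. zero events) are listed as unfittable.

`scripts/acceptance.py --seed S --out F` runs the default full-scale study
and writes the headline quantities as `{"name": {"value": v, "n": n}}`.
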