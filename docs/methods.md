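# Methods

## Setting and data model

The unit of analysis is one survey respondent: a departmental-area stratum
label (surgical or medical discharge), 19 experience items and one
overall-satisfaction item on 1–5 Likert scales, and optional socio-demographics
(sex, age group/age, education, perceived health, chronic condition, admission
type, length of stay).  Respondents may stop the questionnaire at any point,
so every field is individually missing-able and every analysis states the
variables it completes on.

**Missing-data policy.** Listwise deletion on exactly the variables entering
each analysis (outcome plus predictors for the regression; the same
complete-case population supplies the optimizer's baseline item means, keeping
coefficients and baselines on one population).  Percent denominators in the
descriptive table are the nonmissing counts within stratum and variable.

**Descriptive comparisons.** With exactly two strata, categorical demographics
are compared by Pearson chi-square (no continuity correction) and continuous
variables (age, length of stay, and the satisfaction mean) by the Welch
unequal-variance t-test.  P-values are retained at full precision and also
rounded to three decimals for display, where `0.000` means `< 0.0005`.

## Ordinal regression

Satisfaction follows a cumulative-logit proportional-odds model,
P(Y ≤ k | x) = F(κ_k − Σ_j b_j x_j), with the logistic CDF F, four increasing
cutpoints and no separate intercept.  Item responses enter as continuous 1–5
scores — one coefficient per item.  Under this sign convention, positive b_j
means better experience → higher satisfaction.

Estimation details:

* **Likelihood and score** are computed analytically and vectorized; the
  per-record probability is evaluated through the stable one-sided forms
  F(A) at the bottom category and 1 − F(B) at the top.
* **Optimization**: BFGS on a reparameterized vector (b, κ_1, log of cutpoint
  gaps) guaranteeing κ monotone, started deterministically at b = 0 with κ at
  the logits of the cumulative outcome proportions (the exact intercept-only
  MLE, so null fits converge in zero iterations and repeated fits are
  bit-identical without seeds).  A Newton polish on the original parameters —
  Hessian by central differences of the analytic score — drives the score norm
  below 1e-8; `converged` requires norm < 1e-6, with an iteration cap of 200.
* **Uncertainty**: inverse observed information at the optimum; two-sided Wald
  p-values per coefficient.  An independent cross-check against statsmodels'
  `OrderedModel` (same parameterization) agrees to ~1e-4 in coefficients and
  ~1e-6 relative in standard errors on test data.
* **Degenerate outcomes**: a category of the 1–5 scale with zero observations
  leaves its cutpoint unidentified, so `fit_proportional_odds` refuses with an
  error advising an explicit collapse.  Strongly top-skewed samples regularly
  leave the bottom category empty (about one replicate in ten at n = 5,000
  under the default surgical scenario), and proportional-odds coefficients are
  invariant under merging adjacent outcome categories, so
  `fit_collapsed_proportional_odds` performs the collapse explicitly: it fits
  on the observed level set, logs the dropped levels, and records them in the
  fit's `categories` field.  The pipeline and the recovery harness use this
  entry point.

The anomalous negative coefficient on the cleaning item in the published
estimates (higher reported cleanliness associated with lower satisfaction,
identically signed in both areas) most plausibly reflects reverse keying in
the source instrument; the codebook carries a polarity flag as metadata but
responses are never recoded automatically.

## Improvement optimization

Given a fit and the stratum baseline means x̄, the solver picks percent
improvements δ_j (multiplicative on the baseline) minimizing total effort
Σ_j δ_j subject to a target percent gain t in predicted satisfaction and box
constraints 0 ≤ δ_j ≤ min(c, 100·(5 − x̄_j)/x̄_j) — the configured cap
(default 15%) tightened by the scale ceiling, which is why items with large
coefficients but near-ceiling baselines can drop out of the priority tables.

Predicted satisfaction is evaluated at the stratum mean vector ("mean
patient").  Two metrics are offered: the expected score Σ_k k·p_k (default)
and the top-box probability P(Y = 5).  Both are strictly increasing functions
of the linear predictor η = Σ_j b_j x̄_j (1 + δ_j/100), which is **linear** in
δ.  The constraint therefore reduces to η ≥ η_req (η_req found by 1-D root
finding on the metric), and the problem becomes a continuous knapsack: each
percentage point of δ_j buys w_j = b_j x̄_j / 100 units of η.  The exact
optimum fills items in decreasing w_j (ties broken by larger b_j, then
questionnaire order) until the requirement is met — several items pinned at
their caps plus one fractional marginal item.  The solver implements this
greedy fill directly; its correctness contract is oracle equivalence, checked
against an exhaustive grid search (`brute_force_oracle`, ≤ 4 items, default
grid 0.1pp) on random instances.

Design choices made where the formulation was genuinely open:

* **Objective Σ δ_j** (total percentage-point effort, uniform unit costs).
  This reproduces the characteristic cap-plus-fractional solution pattern that
  minimizing the item count would not; no cost structure is modelled, and
  per-item cost weights are an explicit non-default extension point.
* **Eligible set**: items with b_j > 0 by default (raising a non-positive
  coefficient cannot increase predicted satisfaction under the model); no
  significance filter is applied.  Configurable per problem.
* **The 15% figure is a per-item cap** on improvement, not a cap on the
  satisfaction gain; the feasibility machinery handles the latter.
* **Feasibility**: the bound is the gain with every eligible item at its
  effective cap; targets above it return `infeasible` with the all-caps vector
  as a diagnostic.  Algebraically the bound can never exceed
  100·(5 − S0)/S0 for baseline score S0, so with S0 ≈ 4.6 gains beyond ~8.7%
  are impossible and in practice the cap keeps the bound near 5–7%.
* **Display rounding** (1 decimal in priority tables) never feeds back into
  comparisons or solutions.

## Synthetic surveys

Real respondent-level data are confidential, so the generator emulates their
documented structure and is itself first-class, tested code:

* **Items**: latent standard-normal traits with equicorrelation ρ (default
  0.4, a moderate inter-item correlation typical of PREM batteries),
  discretized through per-item thresholds.  Thresholds are equally spaced cuts
  (gap 0.8 latent SD) shifted by a scalar solved analytically so each item's
  expected score equals its target mean — the implied mean is strictly
  monotone in the shift, so Brent root finding is exact.  Discretization
  attenuates the latent correlation (ρ = 0.4 → ≈ 0.29 on the scores);
  `expected_item_correlation` computes the exact attenuated value via
  bivariate-normal orthant probabilities and is what realized correlations are
  tested against.
* **Satisfaction**: drawn from the proportional-odds model at the realized
  item scores, making the generator exactly model-consistent with the
  estimator — parameter-recovery results measure the estimator, not model
  misspecification.
* **Default scenarios** carry the published per-area coefficients, cutpoints
  and regression sample sizes (5,434 surgical / 1,867 medical).  Item-level
  means are unpublished; defaults are drawn deterministically from the seed,
  uniform on [4.2, 4.8] — the top-skewed range these surveys report (simulated
  satisfaction means land near the published 4.6/4.5).  They are stand-ins,
  not estimates.  The default scenario generates the analysis population
  directly (dropout 0), since its n is the complete-case regression n;
  drop-off is enabled per scenario.
* **Drop-off** is monotone: with per-item probability r a respondent quits and
  never returns; all later items become missing, and the satisfaction item —
  which closes the questionnaire — is then missing with configurable
  probability (default 1).
* **Determinism**: one `numpy` Generator per stratum seeded from
  (scenario seed, stratum index); identical seeds give bit-identical datasets.
  Latent draws precede the satisfaction uniforms, so two scenarios differing
  only in coefficients share common random numbers — used to verify that
  increasing any b_j weakly increases simulated satisfaction respondent by
  respondent.

What passing tests on these data do *not* show: robustness to non-monotone
missingness, response styles, mode or interviewer effects, non-equicorrelated
item structure, or violations of proportional odds — none of which the
generator emulates.

## Problem sizes in the checked results

The recovery study uses 50 replicates of n = 5,000 under the surgical default
scenario (bias of each coefficient < 0.05, pooled 95% Wald coverage within
[0.92, 0.97]); solver–oracle agreement uses ten random 3-item instances at
grid step 0.1pp (tolerance 0.2pp); pipeline determinism and report round-trips
use smaller simulated surveys (n in the hundreds to low thousands).  These
sizes were chosen to exercise the asymptotics the contracts describe while
keeping the default test run quick.

## Known limitations

* Improvements act on item *means* of ordinal responses; working with full
  response distributions would need a different formulation.
* Uniform unit costs: a 1% improvement is assumed equally costly on every
  item.
* Mean-patient evaluation: the satisfaction functional is evaluated at the
  stratum mean vector, not averaged over patients.
* No proportional-odds assumption test is run; no survey weights, multilevel
  structure, or partial proportional odds.
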