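# Methods

This note documents the models, the synthetic-cohort generator, the
numerical choices, and the limits of what the test suite demonstrates.

## 1. Outcome model

The unit of analysis is the post-baseline person-year. For participant *i*
in study year *t* ∈ {1, 2, 3},

```
y_it ~ Bernoulli( logit⁻¹( α + u_t + z_itᵀ β ) )
```

* `z_it` stacks three covariate classes. **Demographic**: age, baseline
  working status, worked-in-past-2-years, education (one-hot against a
  less-than-high-school reference), race (against a white reference), stable
  housing, vehicle access, study arm (full/basic service against usual
  services). **Function**: the seven WD-FAB scale scores carried as values
  (Basic Mobility, Upper Body, Fine Motor, Communication & Cognition,
  Resilience & Sociability, Interpersonal Interactions, Mood & Emotions),
  plus presence indicators for the Community Mobility Drive / Ride /
  Wheelchair scores. **Medical**: CSI, BMI, DAST, AUDIT and ~25
  ER/inpatient/outpatient utilization counts.
* Every continuous predictor enters twice: its baseline value
  (standardized by the observed-cell mean/SD) and its change from baseline
  for that year (standardized by the mean and SD of observed differences,
  pooled across years). Binary indicators and dummies stay 0/1. The
  standardizer is fitted once per analysis dataset (post-filter) and shared
  by all submodels so effect sizes are comparable.
* Priors: `α ~ N(0, 2.5)`; `β_j ~ N(0, λ)` with `λ ~ HalfNormal(1)` (a
  shared shrinkage scale, which also regularizes separated data — no Firth
  correction is needed); year intercepts `u_t ~ N(0, τ)`,
  `τ ~ HalfNormal(1)`. Both hierarchy components can be switched off or
  fixed through `LogisticModelSpec`.

Covariate submodels restrict the classes: `demo`, `demo+fab`, `demo+med`,
`full`.

## 2. Missing covariates: exact marginalization

Participants miss 0, 7, 14 or 21 of the 28 functioning measurements
(all seven scales blank together in 0–3 follow-up waves). After filtering to
a tolerance (14 by default; 0 and 7 supported), the remaining missing
standardized cells are modeled, not dropped:

```
z_miss,(i,j) ~ N(μ_j, σ_j)
```

per column *j*, with `μ_j ~ N(0,1)`, `σ_j ~ HalfNormal(2)` learned from the
observed cells of the same column. Because the latents enter the likelihood
only through `z_itᵀ β`, their joint contribution to row *i* is a scalar
Gaussian `δ_i ~ N(m_i, v_i)` with `m_i = Σ_j∈miss(i) β_j μ_j`,
`v_i = Σ β_j² σ_j²`, and the row likelihood

```
p(y_i | θ) = ∫ Bern(y_i | logit⁻¹(η_i + δ)) N(δ; m_i, v_i) dδ
```

is evaluated by 15-point Gauss–Hermite quadrature. This marginalization is
exact up to quadrature error and removes all latent cells from the sampling
space. Per-draw imputations are reconstructed afterwards without
approximation: `δ_i | y_i, θ` is sampled by inverse-CDF on a 128-point grid
spanning ±6 prior SDs, and the cell values by Gaussian conditioning of
`z | βᵀz = δ`. The test suite verifies the whole scheme against brute-force
3-D grid integration over (α, β, z_miss).

Pointwise log-likelihoods for LOO use each draw's imputed values
(`log Bern(y_i | p_i^(s)(z^(s)))`, not the quadrature marginal): for a joint
posterior with per-observation latents, `1 / p(y_i | θ, z_i)` is exactly the
importance weight that converts joint-posterior draws into draws from the
leave-one-out posterior, so PSIS-LOO remains valid.

## 3. Inference

No probabilistic-programming framework is used; the samplers are part of the
package.

* **HMC** (default for the GLMs): static-trajectory Hamiltonian Monte Carlo
  with analytically derived gradients (verified against finite differences
  in the tests), randomized trajectory lengths (uniform 1..20 leapfrog
  steps), dual-averaging step-size adaptation targeting 0.8 acceptance, and
  a diagonal mass matrix estimated in the middle warmup window. Defaults:
  4 chains × 1,000 draws after 1,000 warmup iterations. All scale
  hyperparameters are sampled on the log scale and the coefficient blocks
  use the **non-centered parameterization** (`β = λ·β̃`, `u = τ·ũ`,
  `δ = s·δ̃`) to avoid the hierarchical funnel. Chains start from an L-BFGS
  MAP point computed with the log-scale hyperparameters frozen (their joint
  mode is degenerate). Convergence is summarized by split-R̂ and ESS
  (via arviz) plus divergence counts; a failed fit is returned flagged with
  a warning, never silently.
* **Variational** (optional for GLMs, default for the BNN): mean-field
  Gaussian VI maximizing the reparameterized single-sample ELBO with a
  hand-rolled Adam optimizer. VI underestimates posterior spread; for the
  GLMs it is a speed option and the reported credible intervals should be
  read accordingly.

## 4. Nonlinear models

* **Piecewise-linear Bayesian GLM.** Partition covariates (default:
  baseline working status and baseline Communication & Cognition — the
  original partitioning variables are not published, so this is a
  configurable package default) define quantile bins (terciles by default;
  binary columns split naturally). Each product cell *c* has effective
  coefficients `β_c = β_global + Σ_d δ_{d, level_d(c)}` including a
  per-level intercept deviation — random intercepts and random slopes by
  additive decomposition. Deviations carry zero-mean shrinkage priors
  `δ ~ N(0, s_d)`, `s_d ~ HalfNormal(0.5)`; no sum-to-zero constraint is
  imposed, so individual components are only weakly identified and tests
  compare cell-level sums, not raw components. Levels with fewer than 2 rows
  are merged into a neighbor with a warning. With `deviation_scale = 0` or a
  single-cell partition the density is *identical* (tested to machine
  precision) to the plain logistic model.
* **Bayesian neural network.** One hidden tanh layer
  (`logit p = w₂ᵀ tanh(W₁ z + b₁) + b₂`), `N(0,1)` priors on all weights;
  hidden width 12 by default with a PSIS-LOO scan over widths 2–20
  (`width_scan`, argmax elpd with one-SE tie-breaking toward smaller
  widths). The smooth activation keeps gradients stable. Missing cells are
  per-cell latents with standard-normal priors on the standardized scale,
  fitted jointly by VI (here the latents enter nonlinearly, so the
  quadrature collapse is unavailable; fixed standard-normal latent priors
  are used rather than learned hyperparameters, consistent with columns that
  are standardized to mean 0/SD 1). Each restart (5 by default) runs L-BFGS
  to a mode and then VI around it; the best trailing-average ELBO wins.

## 5. Evaluation

* **PSIS-LOO.** Raw weights `−loglik[:, i]`; the
  `M = min(⌈0.2·S⌉, ⌈3√S⌉)` largest are replaced by expected order
  statistics of a generalized Pareto distribution fitted to the exceedances
  (profile-posterior estimator with the standard shape regularization
  `k̂ ← (n·k̂ + 5)/(n + 10)`), truncated at the raw maximum and normalized.
  `k̂ > 0.7` counts are surfaced in every report; below 25 draws the
  smoothing falls back to truncated importance sampling. The implementation
  is cross-checked against arviz's `psislw` (agreement to ~1e-12) and
  against exact refit-LOO by dense grid integration on an n=40 logistic fit
  (max pointwise discrepancy ~0.005 at S=4,000).
* **Curves.** ROC with group-together tie handling and trapezoidal AUROC
  (equals the Mann–Whitney statistic exactly, tested on random tied sets);
  precision–recall with step-wise (right-continuous) AUPRC, since linear
  PR interpolation is biased. Model comparison requires identical
  observation sets and ranks by LOO-AUROC with an elpd tie-break.

## 6. Synthetic-cohort generator

The generator runs the analysis model forward and is calibrated to the
published SED-PUF summary statistics (`fabwork.tables`):

* WD-FAB trajectories: baseline `N(mean, SD)` per scale; year-*t* value =
  baseline + independent change draw with that year's printed change
  moments. The shared baseline induces within-participant correlation;
  no further serial structure (e.g. AR(1)) is modeled because only marginal
  change moments are published.
* Medical variables: independent per-year draws — negative binomial matched
  to the printed mean/SD for counts (Poisson fallback, logged, when the
  target is under-dispersed), ≥0-truncated normal for score-like variables
  (CSI, BMI, DAST, AUDIT) with the location solved numerically so the
  truncated mean equals the printed mean.
* Community Mobility presence flags: per-year Bernoulli draws with the
  published per-year presence rates; pooled, these reproduce the ~60%
  (Drive) and ~80% (Transit) marginal missingness.
* Demographics: age uniform on the 18–49 recruitment range; categorical
  splits are plausible defaults (no frequency table is published) and
  config-overridable; arms split 1/3 each.
* Outcome: `y ~ Bernoulli(logit⁻¹(α_t + zᵀβ_true))` on a truth design
  standardized by the *population* moments. The default `β_true`
  (`fabwork.tables.DEFAULT_TRUE_COEFFICIENTS`) reproduces the reported
  ordering of top predictors qualitatively: baseline working status
  dominant; function changes and Drive-score presence positive; ER
  utilization negative. The per-year intercepts are calibrated once, by
  root-finding on a fixed internal reference cohort (n=50,000, internal
  seed independent of the user seed), so the population steady-work rates
  match the printed 0.155 / 0.192 / 0.173.
* Missingness: a participant-level pattern from {0, 7, 14, 21} (weights
  0.55/0.20/0.15/0.10 by default — the published figure shows the shape but
  not the counts) blanks all seven scales in randomly chosen follow-up
  waves, completely at random. Informative missingness is out of scope. The
  pre-missingness values are retained in a truth channel for oracle tests.

**What passing tests do and do not show.** The generator matches the
published *marginal* moments and missingness structure; it does not
reproduce the real joint dependence between function, medical and
demographic variables (they are generated independently), real serial
dynamics, or any informative-missingness mechanism. Tests therefore
demonstrate the correctness of the *methods* (posterior computation,
marginalization, LOO, curve estimation, recovery of a known mechanism), not
substantive conclusions about the SED cohort itself.

## 7. Numerical choices and degenerate inputs

* Gauss–Hermite order 15 (config-settable); rows with `v_i = 0` bypass the
  quadrature.
* Credible intervals are central 2.5%–97.5% linear-interpolation empirical
  quantiles.
* Constant columns are rejected by the standardizer by name; participants
  without a baseline row raise a structural error listing ids; single-class
  outcomes are rejected by the curve estimators; a constant-exceedance GPD
  tail returns the boundary without crashing; log-density evaluations at
  numerically diverged points return −∞ rather than raising.
* Problem sizes in the test suite are scaled to keep the full run fast:
  recovery studies use 50 replicates at 1,000 participants (demographic
  covariates), the headline function-vs-medical comparison uses 10
  replicates at 400 participants with a trimmed medical block (at small n
  the rare-utilization counts are all-zero and are dropped via
  `reduced_config`), and oracle comparisons use n=40–60 with dense grids.
  These sizes are package defaults for testing, chosen so the suite gives
  tight Monte-Carlo bands; the models themselves run at full cohort scale.

## 8. Known limitations

* The hierarchical structure and priors of the original analysis are not
  fully published; the ones here are documented package defaults, not claims
  about the original (the same applies to the BNN's inference method and the
  piecewise model's partitioning covariates).
* Imputation is marginal per column; cross-column correlation of missing
  cells is not modeled.
* LOO treats the person-year observation as the unit, matching a
  per-observation predictive evaluation; participant-level leave-one-out
  (all of a participant's years held out together) would be a stricter test
  of between-person generalization and is a possible extension.
* VI credible intervals (BNN, optional GLM mode) understate uncertainty
  relative to MCMC.
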