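# fabwork

Bayesian analysis of **steady work** in longitudinal disability cohorts:
does *functional* improvement (self-reported WD-FAB scores) predict
returning to steady employment better than *medical* improvement
(symptom scales and health-care utilization)?

The package re-implements, as a tested and reusable pipeline, the analysis
design used on the Supported Employment Demonstration Public Use File
(SED-PUF) — a restricted-access panel of 2,944 recently denied disability
benefit applicants with mental health conditions, followed annually for
three years. Because the SED-PUF cannot be redistributed, the package ships
a **synthetic-cohort generator** calibrated to the published summary
statistics of that file, so every downstream stage is runnable and testable
end to end without a data download.

## The model

For participant *i* in study year *t* ∈ {1, 2, 3}, steady work (employment
at least half-time, as coded in the SED data) is modeled as

```
y_it ~ Bernoulli( logit⁻¹( α + u_t + z_itᵀ β ) )
β_j  ~ Normal(0, λ),   λ ~ HalfNormal(1)        (shared shrinkage)
u_t  ~ Normal(0, τ),   τ ~ HalfNormal(1)        (year-level intercepts)
```

Each predictor enters twice — its baseline value and its change from
baseline for that year — and all continuous predictors are standardized so
effect sizes are directly comparable. Community Mobility scale scores,
which are structurally missing for non-drivers / non-transit-users
(~60% / ~80% missing), enter only as presence indicators. Remaining missing
scale scores (participants miss 0, 7, 14 or 21 of the 7 × 4 functioning
measurements) are handled *inside* the model: each missing standardized cell
carries a latent value `z_miss ~ Normal(μ_col, σ_col)` with hyperparameters
learned from the observed cells, and the latents are **marginalized exactly**
during inference — they enter only through the linear predictor, so their
joint contribution per row collapses to a one-dimensional Gaussian integral
evaluated by Gauss–Hermite quadrature inside a hand-rolled Hamiltonian Monte
Carlo sampler (non-centered parameterization, dual-averaging step-size
adaptation, diagonal mass estimation).

Four covariate submodels are compared — `demo`, `demo+fab`, `demo+med`,
`full` — plus two nonlinear replications: a **piecewise-linear Bayesian GLM**
whose per-region coefficients are an additive decomposition
`β_cell = β_global + Σ_d δ_{d, level}` with shrinkage priors on the
deviations, and a **shallow Bayesian neural network** (hidden width 12 by
default, scanned over 2–20) fitted by mean-field variational inference.

Models are ranked by **PSIS-LOO** cross-validation: Pareto-smoothed
importance sampling yields each observation's leave-one-out predictive
probability and log-density (with the k̂ tail diagnostic), from which
LOO-cross-validated ROC and precision–recall curves and their areas are
computed.

## Worked example

```python
import fabwork

# a small synthetic cohort (the default configuration is the full n=2944 study)
config = fabwork.cohort.reduced_config(400, seed=11)
panel = fabwork.generate_cohort(config)

design, params = fabwork.prepare_design(panel, tolerance=14, covariate_set="demo+fab")
spec = fabwork.LogisticModelSpec(draws=500, warmup=500, chains=2)
results = fabwork.SteadyWorkLogistic(design, spec).fit(seed=7)

print(results.odds_ratios().top(3)[["name", "or_mean", "or_2.5%", "or_97.5%"]])
loo = results.loo()
roc = fabwork.roc_curve(loo.p_hat, design.y)
print(f"elpd_loo = {loo.elpd_loo:.1f} (se {loo.se:.1f}), "
      f"LOO-AUROC = {roc.auc:.3f}, khat>0.7: {loo.n_high_khat}")
```

which prints:

```
                    name   or_mean   or_2.5%  or_97.5%
0       baseline_working  1.772654  1.208316  2.569575
1              has_drive  1.442588  1.070920  1.961788
2  fab_resilience_change  1.423388  1.182864  1.731322
elpd_loo = -407.3 (se 20.1), LOO-AUROC = 0.704, khat>0.7: 0
```

Baseline working status is the strongest predictor, followed by having a
Community Mobility Drive score and the change in Resilience — function-class
predictors dominating, which is exactly the synthetic generator's true
mechanism and mirrors the ordering reported for the real cohort. The odds
ratios are
per standard deviation of the predictor; `elpd_loo` is the LOO expected log
predictive density and the AUROC is computed from leave-one-out predictive
probabilities, not in-sample fits.

The same stages are scriptable from a shell:

```bash
fabwork simulate --seed 17 --out panel.parquet
fabwork prep --panel panel.parquet --tolerance 14 --covariates full --out design.parquet
fabwork fit --design design.parquet --model glm --draws 1000 --seed 7 --out post/
fabwork evaluate --post post/ --design design.parquet --out eval/
fabwork run --config run.json     # the whole pipeline + comparison report
```

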