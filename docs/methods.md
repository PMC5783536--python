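# Methods

## The two-part (hurdle) model

Weekly leisure-time physical-activity minutes are semicontinuous: a point
mass at exactly zero (no activity) and a continuous, right-skewed positive
part. The package models the two processes independently:

1. **Zero process.** X_i = 1{Y_i > 0} is Bernoulli with
   logit(p_i) = x_i'α.
2. **Duration process.** Conditional on X_i = 1, Y_i is gamma with mean
   μ_i = w_i'β (identity link) and variance μ_i²ν², i.e. shape k = 1/ν² and
   scale μ_i ν². ν is the coefficient of variation of the duration around
   its conditional mean.

Zeros are *structural*: the gamma density is evaluated only on the positive
rows, never censored or truncated at zero. The likelihood therefore factors,
L(p, μ, ν) = L(p) · L(μ, ν), the parts share no parameters, and maximising
them separately is the exact joint maximum. The test suite verifies the
factoring identity to 1e-9 relative and the joint optimum against a generic
simplex optimiser. The designs of the two parts may differ (`X` vs `W`);
they default to the same matrix.

Assumptions worth stating: every zero is a true "no activity" report (no
measurement-floor zeros); positives are conditionally gamma with a *common*
ν across covariate profiles; observations are independent (no survey design,
clustering or weights).

## Fitting

* **Logistic part** — Newton-Raphson (equivalently IRLS) from a zero start;
  convergence when the relative log-likelihood change is below 1e-10 (max
  100 iterations), with step-halving to keep the likelihood monotone.
  Perfect or quasi-separation is detected as a coefficient exceeding 30 in
  absolute value (odds ratios beyond e³⁰) while the likelihood still
  improves, and is raised as an error naming the offending column rather
  than returned as a silently huge estimate.
* **Gamma part** — the identity link is not the canonical gamma link, so
  positivity of every fitted mean must be enforced: the start is the OLS
  solution with the intercept inflated to feasibility if needed, and every
  Fisher-scoring step is halved until all w_i'β > 0 and the likelihood does
  not decrease; if no feasible ascent step exists the fit aborts with a
  boundary diagnostic. Two algebraic facts reduce the joint MLE of (β, ν)
  to two cheap stages without changing the estimator: the score for β is
  k·Σ w_i (y_i − μ_i)/μ_i², free of k, so β̂ does not depend on ν; and the
  (β, k) cross-derivative equals that score divided by k, hence vanishes at
  β̂. β̂ therefore comes from Fisher scoring alone (relative log-likelihood
  tolerance 1e-10 *and* a step-size criterion of 1e-9 relative — Fisher
  scoring converges linearly here, so a small likelihood change alone can
  stop short of the optimum), and k̂ solves log k − ψ(k) = mean(y/μ̂ −
  log(y/μ̂) − 1), a one-dimensional root found by safeguarded Newton. The
  pair (β̂, ν̂ = 1/√k̂) is the joint maximiser; the equivalence with a
  generic joint optimiser over (β, log ν) is a test. Dispersion is full
  maximum likelihood, not a moment estimator, because the model is defined
  by its full likelihood. If all residuals vanish (constant outcome) the
  degenerate limit ν → 0 is reported explicitly.
* **Multinomial comparator** — baseline-category logit with inactivity as
  the reference, Newton-Raphson with the same tolerance policy and
  separation rule as the logistic part. Collapsing to two categories
  reproduces the binary logistic fit (tested to 1e-6); the log-likelihood is
  invariant to the baseline choice.
* **Inference** — Wald: covariance is the inverse observed information at
  the optimum (for β the observed-information block is used; in the rare
  event it is not positive definite the expected information is substituted).
  The (β, k) orthogonality at the optimum means the β block inverts on its
  own. Odds ratios exponentiate α entries; gamma coefficients are reported
  as mean differences in minutes/week with significance judged against zero.
  No AIC/BIC appear anywhere: the two compared models do not describe the
  same response variable, so such criteria would not be comparable.

## Design matrices and recoding

Fixed column order `intercept, male, high_school, college, graduate,
age_decades, income_k`; reference levels female and basic education; age is
divided by 10 and income by 1,000 before fitting, so coefficients are per
decade of age and per US$1,000 of income. Complete-case analysis: rows
missing any modelled variable are dropped and counted, never imputed.
Category spellings are case-insensitive with documented canonical forms.
The outcome is consumed as a single weekly total (days × minutes/day via
`weekly_minutes`); sub-domains of activity (walking, moderate, vigorous)
are not distinguished, and no aggregation rule across them is guessed.
The 150 min/week boundary belongs to the upper category ("150 or more");
exact zero is the sole marker of inactivity.

## The synthetic cohort generator

`simulate_covariates` targets the marginals of a large adult occupational
cohort: P(female) = 0.544; age truncated-normal(52, 9.1²) on [35, 74] years;
education shares 0.127 / 0.346 / 0.159 / 0.369 (basic / high school /
college / graduate); income log-normal with mean US$6,505 and log-scale SD
0.8 (chosen to give a realistic right tail; only the mean is published).
Covariates are drawn independently — the joint covariate structure of the
real cohort is not published — and that fact is recorded in the generator's
metadata sidecar; a `dependence_hook` allows users to impose correlations.

`simulate_zig` layers the outcome process on top: Bernoulli activity with
logit(p) = x'α, then gamma minutes with mean x'β and CV ν for the active.
The default slopes are the published adjusted effects (odds ratios 1.70 men,
1.12 per age decade, 1.28/1.72/2.32 education, 1.05 per US$1,000; mean
differences 28.78, 6.20, 19.93/25.81/14.45, 7.58 minutes/week). The
intercepts are not published; they are calibrated numerically on a large
fixed-seed covariate sample (n = 200,000, its own seed, so calibration is
deterministic and independent of the simulation seed): α₀ solves
mean(expit(α₀ + x'α_slopes)) = 0.57, and β₀ makes the p-weighted mean of μ
equal 237 — the mean among the *active* is the p_i-weighted average of μ_i,
which is why the weighting matters. The default ν = 1 reproduces the
qualitative shape of the observed outcome: strong right skew and about 1%
of the active above 1,000 minutes/week. The generator validates that every
μ_i is positive and aborts naming the offending covariate profile otherwise.
The outcome stream is seeded separately from the covariate stream, so the
same seed yields identical covariates under different outcome parameters.

What passing tests on this generator do **not** show: robustness to
covariate dependence, measurement error in self-reported activity
(questionnaire totals are typically overestimates), non-gamma duration
shapes, or any sampling design. The generator targets stated marginals only.

## Recovery experiments

`run_recovery` repeats simulate → fit; replicate r uses seed root + r, so
reports are bit-for-bit reproducible. It aggregates per-parameter bias,
empirical SE and 95% Wald coverage, and fits the multinomial comparator on
the categorised outcome of the same replicates so both approaches face the
same generative truth. Replicate failures are recorded in the report, never
dropped. Experiment sizes used by the tests and the acceptance script —
50–200 replicates at n = 14,823 for the headline effects, 500 replicates at
n = 5,000 for coverage, 40/20/10 replicates at n = 1,000/10,000/50,000 for
the consistency check — were chosen as desk-scale defaults that keep
Monte-Carlo error well below the effects being checked.

## Known limitations

* Point predictions only from `predict_mean_time`; no delta-method SEs for
  the unconditional mean.
* No regularisation, survey weights, clustered errors, random effects or
  interaction terms.
* ν is assumed common across profiles; a covariate-dependent dispersion
  would need a different optimiser.
* Wald intervals rely on large-sample normality; at very small n or near
  the positivity boundary they can be optimistic.
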