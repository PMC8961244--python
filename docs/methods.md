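# Methods

## Scope and data model

The package classifies individuals into one of two populations from
complete multivariate repeated measures: Q responses, each observed at the
same P occasions, for N individuals.  All vectors are stacked
response-major with the occasion index fastest — coordinate (q, p) sits at
position (q−1)·P + p — and the coefficient vector follows the same order,
β = (β₁', …, β_Q')' with β_q = (β_q1, β_q2).  Each response carries K = 2
covariates: a time-invariant scalar x_i and the occasion time t_p (log t_p
for the log-linear count model, so occasion times are taken positive,
t_p = p).  Missing or unbalanced occasions are rejected rather than
imputed; the estimators assume complete data.

## The GEE estimator

Marginal means are μ_ipq = f_q(β_q1 x_i + β_q2 t_p) with identity, log or
logit inverse link per response.  β solves U(β) = Σ_i D_i' Ω_i⁻¹ (y_i−μ_i)
= 0 by Fisher scoring, with the Kronecker working covariance

    Ω_i = A_i^{1/2} (R(α) ⊗ R(ρ)) A_i^{1/2},
    A_i = diag(φ_q · v_q(μ_ipq)).

Nuisance parameters are refreshed from Pearson residuals after every
scoring step:

* **Dispersion.** A free per-response dispersion φ_q is estimated for
  gaussian responses (φ̂_q = Σ r²/(NP−K)) and fixed at 1 for Poisson and
  Bernoulli responses.  A single global dispersion would misscale mixed
  panels (a gaussian response with variance 60 next to a Bernoulli response
  would inflate the binary working variance ~60-fold), so the per-response
  convention is used throughout and residuals are standardized per response
  before any correlation moment.  The global scale Σ r²/(NPQ−KQ) is still
  computed and reported.
* **Correlations.** Standard cross-product moment estimators: R(α) is the
  unstructured between-response correlation filled from same-occasion
  cross-response products; ρ comes from adjacent-pair products (AR1) or all
  within-response pair products (exchangeable).  Estimates are clipped to
  (−0.99, 0.99); an estimated R(α) that is not positive definite is shrunk
  toward the identity with the smallest convex weight restoring a minimum
  eigenvalue of 1e−6.  Standardized residuals are winsorized at ±5 before
  the correlation moments: near-degenerate discrete coordinates (fitted
  probabilities close to 0/1, tiny count means) otherwise produce isolated
  huge residuals that pin the estimates at the clip boundary.

Numerical safeguards: per-response independence GLM fits (OLS; log-scale
OLS; ridge-IRLS) initialize β; Fisher steps are damped to a max-norm of 5,
which prevents divergence under quasi-separation of a Bernoulli response;
linear predictors are clipped at ±30 before exponentiation and fitted
probabilities at 1e−6.  Convergence is max |Δβ| < 1e−6 within 100
iterations; non-convergent fits are flagged, and the simulation engine
drops (and counts) such replicates.  The robust covariance of β̂ is the
standard sandwich: bread (Σ D'Ω⁻¹D)⁻¹, meat Σ (D'Ω⁻¹e)(D'Ω⁻¹e)'.

## The maximum-likelihood comparator

The normal-theory arm treats every response as continuous with identity
links and a matrix-normal (Kronecker) covariance Σ_B ⊗ R(ρ): Σ_B is the
free Q×Q between-response covariance carrying all scale, R(ρ) a P×P
correlation matrix (AR1 or CS), which fixes the Kronecker scale ambiguity.
Estimation is coordinate ascent ("flip-flop"): GLS for the mean
coefficients given Σ, the closed-form matrix-normal update
Σ_B = (NP)⁻¹ Σ_i E_i R(ρ)⁻¹ E_i' given R(ρ), and a bounded scalar
likelihood maximization over ρ ∈ (−0.99, 0.99).  Every sub-step maximizes
the exact likelihood in its block, so the log-likelihood is non-decreasing
(verified per iteration in the tests); convergence is a log-likelihood gain
below 1e−6.

In the simulation comparisons the comparator is fitted as a **covariance
pattern model**: group-specific mean coefficients, one common Σ estimated
from the pooled residuals of both groups.  Two features of the study design
force this reading: a comparator with group-specific covariances would
match the GEE quadratic rule under normality, and its linear and quadratic
rules would differ under covariance heterogeneity — whereas the procedure
being compared against exhibits neither property.  A consequence worth
stating: with a shared covariance the quadratic rule reduces exactly to the
linear rule (the tests assert this).  Single-sample fits with a free
covariance remain available and are what the parameter-recovery tests use.

## Discriminant rules

Group fits supply μ̂_ji (each individual's mean under group j, at the
individual's own covariates) and Ω̂_ji (the group's covariance evaluated at
the individual's fitted means, so mean-dependent-variance families get
individual-specific covariances).  The linear rule uses the
degrees-of-freedom-weighted pooled covariance ((n₁−1)Ω̂₁ + (n₂−1)Ω̂₂)/
(n₁+n₂−2); priors are proportional, π̂_j = n_j/N.  Scores are computed with
factored solves (diag(s) C diag(s) form) and stable log-determinants; a
covariance whose condition number exceeds 1e10 receives a ridge of
1e−8 × mean(diag).  A score of exactly zero assigns group 2 (the rule's
strict inequality assigns group 1 only on ">").  Evaluation is
resubstitution: fit on all N individuals, reclassify the same N.

## Synthetic data generator

The generator reproduces the three study cases; its defaults are the study
conditions, not tunables.

* **Normal.** μ_ipq = β_q1 x_i + β_q2 t_p (identity link), x_i ~ N(0,1),
  t = (1, …, P); errors are multivariate normal with covariance
  60 · (R(α) ⊗ R(ρ)) — a common marginal variance of 60.  The
  between-response matrices R(α) are the study's printed configurations
  keyed by (Q, ρ); population 2's coefficients are twice population 1's.
* **Poisson.** log μ_ipq = β_q1 x_i + β_q2 log t_p; dependence is induced
  by a Gaussian copula (NORTA): a latent normal with correlation
  R(α) ⊗ R(ρ) is pushed through Φ and the Poisson quantile function at the
  target means.  The achieved count correlation is attenuated relative to
  the latent one; no Cario–Nelson matching is applied (the tests check the
  attenuation inequality rather than equality).  Population 2's
  coefficients are three times population 1's.
* **Mixed.** The normal case with the last response converted to Bernoulli
  by NORTA thresholding: p_ipq = logistic(β_q1 x_i + β_q2 t_p), and y = 1
  iff the standardized latent normal exceeds its (1−p) quantile, preserving
  the latent correlation linkage.

Covariance heterogeneity (Ω₁ = 3Ω₂) scales population 1's generating
covariance by 3; population 2 keeps variance 60.  A copula carries no
scale, so for counts the heterogeneous arm differs only through the group
coefficients.  Group sizes follow the 1:1 and 2:3 splits (N = 80 gives
(40, 40) and (32, 48)).  A `separation_scale` field interpolates the group
contrast (0 = identical populations); it exists for calibration checks and
is 1 under the study conditions.

What the generator does **not** emulate: missing visits and dropout,
covariate measurement error, non-normal covariates, more than two groups,
and real-data link misspecification.  Passing tests therefore demonstrate
correctness of the estimators and rules under the stated generating
mechanisms, not robustness on arbitrary clinical data.

## Monte Carlo engine and problem sizes

A summary cell (distribution, Q, P, estimator, rule, structure) averages
resubstitution accuracy over a collapsed 24-point sub-grid — N ∈ {80, 140,
200} × ratio {1:1, 2:3} × ρ ∈ {0.3, 0.7} × heterogeneity {1×, 3×} — with
equal weights (the study states no weights) and R replicates per
sub-condition.  Replicate seeds derive from
SeedSequence([master, condition-key integers, replicate]), so any cell or
single replicate is independently reproducible; grid runs append per-cell
CSV rows and resume past completed cells.  The package default is R = 500;
the test suite uses R = 6 and `scripts/acceptance.py` R = 25 (600
replicates per cell, Monte Carlo standard errors ≈ 0.002–0.004, an order of
magnitude below the 0.05 comparison band) — desk-scale settings chosen so a
full verification completes in minutes on one CPU.

## Known limitations

* The quadratic rule applies gaussian Mahalanobis/log-determinant geometry
  to discrete coordinates.  When a Bernoulli response is strongly saturated
  (fitted probabilities near 1, as the mixed-type design produces at later
  occasions), rare opposite outcomes receive weight p²/v far exceeding the
  true log-likelihood ratio, and the group log-determinant gap on the
  binary block systematically favors the saturated group.  Mixed-type
  quadratic-GEE accuracy is therefore noticeably below its linear
  counterpart here, unlike in the normal and Poisson cases.
* Working-correlation estimators are method-of-moments, not ML; with very
  small groups (n₁ = 32) the shrinkage guard on R(α) activates
  occasionally.
* Only two groups, complete data, one scalar covariate plus time; no QIC
  structure selection.
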