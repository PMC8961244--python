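# rmda — repeated measures discriminant analysis via multivariate GEE

Classifying individuals into one of two populations from **multivariate
longitudinal data** — Q response variables (continuous, count and/or binary)
each measured at P common occasions — is a recurring problem in clinical
cohort studies (e.g. predicting which newly diagnosed epilepsy patients will
become refractory from repeated measurements of seizure severity, drug count
and quality of life).  Classical linear/quadratic discriminant analysis
ignores the longitudinal covariance structure and leans on multivariate
normality, which binary and count responses violate.

This package implements **repeated measures discriminant analysis (RMDA)
built on multivariate generalized estimating equations**, together with the
normal-theory maximum-likelihood comparator, and a Monte Carlo engine that
evaluates both over a factorial simulation design.

## Model

For individual *i*, stack the responses response-major,
`y_i = (y_i1', …, y_iQ')'` (length *PQ*), with marginal means

```
μ_ipq = f_q(x_ip' β_q),        β = (β_1', …, β_Q')'
```

where `f_q` is the response-specific inverse link (identity / log / logit)
and each response has K = 2 covariates (a time-invariant scalar x_i and the
occasion time t_p).  β solves the generalized estimating equations

```
U(β) = Σ_i D_i' Ω_i⁻¹ (y_i − μ_i) = 0,
Ω_i  = φ A_i^{1/2} ( R(α) ⊗ R(ρ) ) A_i^{1/2},
```

a Kronecker-product working covariance: `R(α)` is the unstructured Q×Q
between-response correlation, `R(ρ)` the P×P within-response correlation
(AR(1) or compound symmetry), and `A_i` the diagonal of marginal variances
`v_q(μ_ipq)`.  Fisher scoring updates β; moment estimators on Pearson
residuals update (φ, α, ρ); a robust sandwich estimator gives `cov(β̂)`.

Group-specific fits (means μ̂_j and covariances Ω̂_j, with proportional
priors π̂_j = n_j/N) feed the discriminant rules.  Linear rule (pooled Ω̂):
assign to group 1 iff

```
(y − (μ̂₁+μ̂₂)/2)' Ω̂⁻¹ (μ̂₁ − μ̂₂) > log(π̂₂/π̂₁)
```

Quadratic rule (group-specific Ω̂_j): assign to group 1 iff

```
(y−μ̂₂)'Ω̂₂⁻¹(y−μ̂₂) − (y−μ̂₁)'Ω̂₁⁻¹(y−μ̂₁) > log(|Ω̂₁|/|Ω̂₂|) + 2 log(π̂₂/π̂₁)
```

The comparator (`estimator="mle"`) is the classical covariance-pattern
model: Gaussian likelihood with identity links, group-specific mean
coefficients, and a single Kronecker-structured covariance
`Σ̂_B ⊗ R̂(ρ)` estimated from the pooled residuals by a flip-flop
(coordinate-ascent) algorithm.

## Worked example

Simulate a mixed-type panel (two gaussian responses with variance 60 and
one NORTA-derived Bernoulli response; Q = 3, P = 5, N = 140 with a 2:3
group split), fit group-wise GEE models with unstructured-between / AR(1)-
within working correlation, and reclassify:

```python
import numpy as np
from rmda import SimCondition, gen_mixed, build_rule, resub_accuracy

cond = SimCondition(distribution="mixed", Q=3, P=5, N=140, n1=56, n2=84,
                    within_kind="ar1", rho=0.7, heterogeneity=1.0)
panel, design = gen_mixed(cond, seed=7)
rule = build_rule(panel, design, estimator="gee", rule="linear", within="ar1")
acc, per_group = resub_accuracy(rule, panel, design)
print(f"overall accuracy: {acc:.3f}")
f1 = rule.fit1
print("group-1 dispersion per response:", np.round(f1.working.phi_q, 2))
print(f"group-1 within-response rho: {f1.rho:.3f}")
print("group-1 between-response correlations:", np.round(f1.alpha, 3))
```

prints

```
overall accuracy: 0.721
group-1 dispersion per response: [61.14 52.25  1.  ]
group-1 within-response rho: 0.577
group-1 between-response correlations: [0.684 0.231 0.207]
```

The estimated dispersions recover the generating variance (60) for the two
gaussian responses and stay fixed at 1 for the Bernoulli response; the
within-response correlation (0.577) sits below the latent 0.7 because
dichotomizing one response attenuates its achieved correlation.  72%
resubstitution accuracy for this condition is typical of the mixed-type
design.

The same model is available as a scikit-learn classifier on a flat feature
matrix (stacked responses plus the covariate as the last column):

```python
from rmda.discriminant import RepeatedMeasuresClassifier, matrix_from_panel
from sklearn.model_selection import cross_val_score

X = matrix_from_panel(panel, design)
clf = RepeatedMeasuresClassifier(n_responses=3, n_occasions=5,
                                 families=["gaussian", "gaussian", "bernoulli"])
print(cross_val_score(clf, X, panel.group_label, cv=5))
# [0.607 0.821 0.607 0.75  0.714]
```

A command-line interface mirrors the library:

```bash
rmda simulate --config grid.yaml --out cells.csv --reps 50 --seed 1
rmda fit --data panel.csv --estimator gee --rule lda --structure unar --out rule.json
rmda classify --model rule.json --data new.csv
```

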