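# Methods

This note records the statistical models implemented in `panelmix`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a user re-deriving our results
would need to know.

## Models

### Cross-sectional latent class analysis

At each wave, the anxiety score a ∈ [0,2] and aggression score g ∈ [1,4] are
modelled as a K-component mixture of Gaussians with diagonal covariance and
class-specific variances:

    p(a, g) = Σₖ wₖ N(a; μₖ₁, σ²ₖ₁) N(g; μₖ₂, σ²ₖ₂).

The measurement model (conditional independence given class, free variances)
is the minimal one producing the characteristic four-type profile plot; a
variance floor of 1e-4 guards against degenerate spikes. Model selection is
by BIC = −2ℓ + p ln n with p = (K−1) + 2KV free parameters. Classification
quality is summarized by relative entropy E = 1 − Σᵢₖ(−pᵢₖ ln pᵢₖ)/(n ln K).

The four-class solution is mapped deterministically onto named types:
C-DA is the highest-aggression class among classes with above-median
anxiety; DA the highest-aggression class among the rest; GAD the
highest-anxiety class of the remaining two; Np the last. Ties beyond 1e-9
raise rather than guess. The mapping is invariant to class-index
permutations (tested).

### Stationary latent transition analysis

The longitudinal model is a hidden-Markov mixture: subject i carries a
latent type z_t at each of T = 5 annual waves. Assumptions:

* **Measurement invariance** — one set of class-conditional Gaussian
  parameters for all waves, so a type means the same thing at every wave
  (without it, cross-wave transitions are uninterpretable).
* **Stationarity** — one annual transition matrix governs every adjacent
  wave pair; 4-year probabilities are its fourth power.
* **Covariate moderation** — the three binary covariates (cohort, sex,
  friendship class) enter the initial-probability and transition logits as
  main effects, reference class Np:
  P(z_{t+1}=k | z_t=j, x) = softmax_k(β_{jk} + γ_{jk}′x). Main effects are
  the minimal covariate structure consistent with "a three-covariate
  stationary model"; wave-by-covariate interactions would break
  stationarity. Whether covariates should also moderate the measurement
  model is an open design question; we hold measurement fixed.

Estimation is EM. The E-step runs exact scaled forward–backward recursions
vectorized over subjects; missing indicator cells contribute likelihood one,
so a fully unobserved wave yields the transition-propagated prior as its
posterior (tested against brute-force path enumeration at 1e-10). The
M-step updates measurement parameters in closed form and each logit block by
weighted multinomial-logistic minimization (L-BFGS with analytic gradient,
ridge 1e-8; separation triggers a ridge-1e-3 refit with a warning). BIC uses
n = number of subjects. Multistart defaults: 30 starts seeded from quick
pooled cross-sectional mixtures; convergence at relative log-likelihood
change < 1e-6, at most 1000 iterations, error on non-convergence.

### Friendship-quality LCGA

Latent class growth analysis of support, negative interaction and power
(each 1–5) over waves coded t = 0..4: within class k, dimension d follows
the quadratic mean curve β₀ₖ𝒹 + β₁ₖ𝒹 t + β₂ₖ𝒹 t², with independent
homoscedastic Gaussian residuals and zero within-class growth-factor
variance (that is what distinguishes LCGA from a general growth mixture).
Class 0 is always the class with the higher mean support curve. The
enumeration test is a **parametric bootstrap LRT**: simulate B datasets from
the fitted K₀ model at the observed cells, refit both models per replicate,
p = (1 + #{boot ≥ observed})/(B+1). We use a bootstrap LRT because the
analytic reference distribution of mixture LRTs is nonstandard; the null
calibration of the test is verified by simulation in the test suite.

### Encompassing-prior Bayes factors

Each parameter group (the four class shares of a subgroup at a wave; a
4-year transition row) is a multinomial probability vector with a
Dirichlet(1,…,1) prior — the neutral encompassing prior — and conjugate
posterior Dirichlet(1 + counts). Counts may be fractional: transition rows
are converted to expected contingency counts (wave-1 type count × the
renormalized 4-year row) and used unrounded, since rounding discards
information and nothing requires it. A constrained model H (inequalities
and/or about-equality bands |lhs − rhs| ≤ tol over linear combinations of
cell probabilities) is scored by

    BF_H = f/c = P(constraints | posterior) / P(constraints | prior),

estimated from independent Monte Carlo draws (default 10⁶; binomial MCSEs
and a delta-method MCSE for the ratio are reported; an estimated complexity
of zero raises instead of dividing). Bayes factors are floored at .001
before posterior model probabilities are formed; the unconstrained model is
the BF = 1 reference. A hypothesis with a single inequality on exchangeable
cells has complexity ½, so its BF cannot exceed ≈2 — the ceiling is a
feature of the method, not a weakness of the evidence.

**About-equality bands.** "No difference" and "similar change" clauses are
operationalized as |lhs − rhs| ≤ tol with tol = .02 on the proportion scale
by default (configurable per run). The published analyses we mirror do not
state their equality machinery. For the six transition model sets the
conclusions are insensitive to tol. For the two prevalence-change sets they
are not: with *independent* wave-wise Dirichlet posteriors built from the
printed tables, the posterior SD of a cohort or sex difference in prevalence
change (.02–.04) is comparable to any sensible band, so the all-band
"no difference" model retains non-trivial fit and — because its prior
complexity is tiny — a large Bayes factor (measured M1 BFs 137–236 for tol
∈ {.01, .02, .05} in the age set, against 38–53 for the accelerated-
development model). The published analysis evaluated these hypotheses on
the posterior of the fitted longitudinal model, in which wave-1 and wave-5
distributions are estimated jointly from all five waves of the same
subjects and are far more concentrated; that posterior cannot be
reconstructed from the printed marginal tables. We therefore report the
desk-scale numbers as what they are and flag this structural limitation
here rather than tuning the band to chase published values. One further
source inconsistency is worth noting: in the friendship acting-out-versus-
failure panel the published PMPs sum to 1.08 and the "no difference" BF of
.90 contradicts the published transition table itself (acting out .06
versus .25 across friendship groups); our computed PMPs (.001/.90/.10) are
self-consistent.

### Missing data

Little's MCAR test compares pattern-wise observed means with EM estimates of
the grand mean/covariance: d² = Σⱼ nⱼ(ȳⱼ−μ̂ⱼ)′Σ̂ⱼ⁻¹(ȳⱼ−μ̂ⱼ), df = (observed
variables summed over patterns) − (variables); d² ~ χ²(df) under MCAR.
Patterns with fewer than 5 cases are pooled into a residual pattern whose
observed set is the intersection of its members' observed sets (dropped if
empty) — pooling avoids singular per-pattern estimates. The MVN EM estimator
(mean/covariance MLE under arbitrary missingness) is implemented here
because no installed package provides it. Imputation replaces missing cells
by EM conditional means, fit separately per cohort (the cohorts differ in
level and trend), clipped to the scale ranges; imputed cells stay flagged in
the panel's observed mask. Single imputation understates uncertainty;
multiple imputation is out of scope.

## The synthetic-data generator

`default_study_config()` encodes the study conditions: cohort sizes 923/390,
wave-1 type shares equal to the packaged class-size table per cohort, sex
ratios 50.7%/43.3% male, a 20.6% poorer-quality friendship class, per-wave
attrition hazard .003 (≈1.2% of subjects lost across the five waves,
monotone: once gone, gone), and annual transition matrices obtained by
minimizing ‖M⁴ − T‖_F over row-stochastic M (softmax parameterization,
L-BFGS) against the packaged 4-year tables per cohort — the annual matrix
itself is not published, so this fourth root is a calibration device, not a
reconstruction. Indicators are truncated Gaussians (resampling, not
clipping, so no probability mass piles up at the scale ends).

Class profiles (anx, agg means): GAD (1.05, 1.45), DA (0.40, 2.30),
C-DA (1.05, 2.90), Np (0.35, 1.38), with variances .04–.16. Two reported
facts guided this choice: per-wave BIC must select exactly four classes at
n = 1313 (reported margin ≥ 257), and classification entropy should be high
(reported .87). With truncated Gaussians these conflict: profiles
overlapping enough for entropy .87 put class means < 1.5 SD from a scale
bound, and the truncation spike then makes BIC add a spurious boundary
class. We kept means ≥ 1.6 SD inside the bounds, which preserves the
four-class BIC selection (6/6 calibration replicates) at the cost of a
higher entropy (≈ .94). Friendship curves give the higher-quality class
more support and less negativity/power, with residual SDs .80–.95, which
reproduces the reported LCGA entropy (.92 vs .91) and the 79.4/20.6 split.

What the generator does **not** emulate: item-level responses (scale means
are drawn directly), MAR/MNAR missingness, within-person correlation of
measurement errors across waves, covariate effects on transitions beyond
cohort (sex and friendship effects are zero in the default truth — useful
for null-recovery checks, but it means default simulations cannot
demonstrate detection of sex/friendship moderation), and the skewness of
real Likert scale scores. Passing recovery tests therefore show correctness
of the estimators under the model, not robustness to real-data violations.

## Problem sizes used by the test suite

Simulation-backed tests are sized to run on one CPU in minutes: MCAR null
calibration uses 200 replicates of n = 370 panels; transition-parameter
recovery uses one n = 5000 panel (mean absolute error < .03 on annual
transition probabilities); BIC class enumeration uses 8 replicates at
n = 1313; BLRT null calibration uses 80–120 outer replicates with B = 39
bootstrap samples at n = 120 (the acceptance tolerance on the rejection
rate is widened to ±.05–.06 accordingly, 2.5 binomial SEs); Bayesian model
sets run at 2×10⁵ draws in tests and 10⁶ in the acceptance script.

## Known limitations

* End-to-end recovery of 4-year transition matrices at the study's own
  sample size is information-limited for the rare comorbid class: the older
  cohort's C-DA origin row rests on ≈47 expected annual transitions, so
  per-cell errors of .05–.15 are expected and observed (max per-cell error
  .07–.18 across seeds; mean .02–.04). A ±.05-per-cell claim is attainable
  only for the common rows or at larger n.
* The desk-scale prevalence-change Bayes factors differ structurally from
  the published longitudinal-posterior ones (see above).
* Equality constraints are bands, not measure-zero equalities; constraints
  are linear in cell probabilities, so ratio-scale hypotheses (e.g.
  "relative decrease stronger") are not expressible.
* The LTA assumes first-order Markov dependence, no mover–stayer structure,
  and complete covariates.
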