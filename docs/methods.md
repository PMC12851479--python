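# Methods

## Model

Let **x**_ij ∈ S^D be the composition of subject *i* at occasion *j*
(strictly positive parts summing to κ; for daily time use D = 4 behaviours
and κ = 1440 min/day).  Given an orthonormal log-ratio basis with contrast
matrix V (D×(D−1), columns orthonormal and summing to zero),
**z**_ij = V′ ln **x**_ij and the model for the coordinate vector is

    z_ij = X_ij β + b_0i + ε_ij,
    b_0i ~ MVN(0, G),   ε_ij ~ MVN(0, E),   mutually independent,

where every fixed-effect term carries a separate coefficient per
coordinate (there is no pooled intercept), G is the between-subject
covariance of the random-intercept vector across coordinates, and E the
residual covariance across coordinates within a subject-occasion.  In the
stacked-response layout this is exactly a univariate mixed model with
response-indicator dummies, which is how practitioners express it in
general-purpose software; here it is estimated directly.

Assumptions worth stating plainly: a single grouping level (subjects);
random intercepts only, so within-subject dependence over occasions is
compound-symmetric per coordinate pair (no serial/AR structure); residual
covariance homogeneous across occasions; Gaussian coordinates; and no zero
parts — a zero behaviour duration makes log-ratios undefined and must be
handled by a zero-replacement method *before* analysis (the package
refuses such rows rather than imputing silently).

Because all cross-coordinate covariances are estimated, any quantity that
uses the complete coordinate vector — joint F statistics over a term's full
block, olr⁻¹ of coefficient blocks, predictions, subject-level fitted
compositions — is invariant to the basis used to build the coordinates.
Constraining G and E to be diagonal ("unrelated outcomes" model)
reproduces the historical one-model-per-coordinate approach and loses that
invariance; both comparators are implemented for demonstration, along with
per-behaviour raw-minutes models whose predictions do not respect the
constant sum.

## Estimation

With subjects independent, subject *i* with J_i observed occasions
contributes y_i ~ MVN(X_i β, V_i), V_i = 11′ ⊗ G + I ⊗ E.  The implied
spectral identities

    V_i⁻¹ = I ⊗ E⁻¹ + (11′/J_i) ⊗ ((E + J_i G)⁻¹ − E⁻¹)
    log|V_i| = (J_i − 1) log|E| + log|E + J_i G|

reduce each subject's cost to two (D−1)×(D−1) factorisations; subjects
with equal J_i share them.  β is profiled out by generalised least
squares; the REML criterion adds log|Σ_i X_i′V_i⁻¹X_i| to the profiled ML
deviance.  G and E are parameterised by log-Cholesky factors (log
diagonal, free sub-diagonal), which enforces positive definiteness without
constraints; near-singular fitted components are reported as boundary
warnings, never truncated silently.

The criterion and its analytic gradient (standard trace/quadratic-form
identities contracted against the Kronecker structure) are minimised by
L-BFGS-B (ftol 1e-13, projected-gradient tolerance 1e-8, up to 3 jittered
restarts), followed by a damped Newton polish with a finite-difference
Hessian of the analytic gradient.  The polish matters: L-BFGS stops on
relative criterion change, which on a deviance of magnitude ~10³ leaves
covariance parameters ~1e-6 from the optimum — enough to show up at the
1e-6 level in BLUP-based fitted values when two mathematically equivalent
bases are compared.  After polishing, equivalent fits agree to ~1e-10.

Starting values are method-of-moments: per-coordinate OLS residuals are
split into subject means (→ G start) and within-subject deviations
(→ E start), eigenvalue-floored to be positive definite.

Missing occasions are handled by each subject contributing only observed
occasions; a subject-occasion is all-or-nothing across coordinates, since
all D−1 coordinates derive from one composition.  REML is the default and
is required when comparing covariance structures that share fixed effects;
ML must be used for likelihood-ratio tests that change fixed effects (the
package enforces the REML comparability rule).

Verification is dual-route: an independent oracle assembles each subject's
dense V_i with explicit Kronecker products and evaluates the likelihood
via `scipy.stats.multivariate_normal`, and β̂ is re-derived by a dense GLS
solve; the optimised criterion and profiled solution match the oracle to
better than 1e-6 on small fixtures.

## Inference

Per-coefficient Wald t tests and joint F tests use the between-within
("inner-outer") counting rule for denominator degrees of freedom: in the
stacked layout every fixed-effect column varies within subjects, so all
terms share den_df = n_stacked − n_subjects − p_fixed.  This is a counting
approximation — not Satterthwaite or Kenward-Roger, which are out of scope
— and is documented as such; the null simulations below show it is
well calibrated at the sizes studied.  The joint F for a term is
(Lβ̂)′(L V̂ L′)⁻¹(Lβ̂)/rank(L); a Wald chi-square variant is available.
Joint tests over full coordinate blocks are preferred to per-coordinate t
tests, which inflate the familywise type-I error across the D−1
coordinates and are basis dependent.  No multiplicity adjustment is
applied across different terms.

Likelihood-ratio tests between nested covariance structures use a χ²
reference with df equal to the parameter-count difference (6 for
unstructured vs diagonal when D = 4).  Zeroed *correlations* are interior
points of the parameter space, so no boundary mixture is needed; testing a
*variance* to zero would be a boundary problem and is not offered.

## Back-transformation and uncertainty

The inverse transformation olr⁻¹(z) = C(exp(Vz)) maps a term's D−1
coefficients to a composition: the intercept block to the baseline
composition (closed to κ), any other block to a perturbation vector
(closed to 1) interpreted against the neutral element [1/D, …, 1/D] —
parts above 1/D gain time under that condition, parts below lose it.
Predictions are olr⁻¹ of the linear predictor and sum to κ by
construction.  "Average participant" predictions hold numeric covariates
at their sample mean and categorical covariates at their reference level;
both choices are overridable and echoed in output.  Differences between
predicted compositions are reported as clr differences
(clr(a) − clr(b), equivalently clr(a ⊖ b)) — a zero-sum vector whose
positive entries mark relatively higher parts in the first composition;
this reading of a "log-ratio difference" is an implementation choice,
documented here because more than one convention exists in the
compositional literature.

Interval estimates for compositional quantities come from a cases
bootstrap: whole subjects are resampled with replacement (occasions travel
with their subject; duplicates get fresh identifiers so they act as
distinct grouping units), the model is refit per replicate, and empirical
percentile intervals (type-7 quantiles) are taken, defaulting to B = 1000
and 95% coverage.  Replicates that fail to converge are dropped and
counted; above 5% failures the interval is flagged unreliable.  Per-part
intervals are marginal, not joint, and their endpoints need not themselves
form a composition.  A master `SeedSequence` spawns one substream per
replicate, so results are a pure function of (data, spec, quantity, B,
seed) regardless of execution order.

## Synthetic data

The generator draws data from the model itself: b_0i ~ MVN(0, G),
ε_ij ~ MVN(0, E), z = Xβ + b_0i + ε_ij, behaviours = olr⁻¹(z) closed to
κ.  Defaults emulate the longitudinal cohort the method was demonstrated
on — 241 subjects × 5 occasions, 4 behaviours, categorical occasions
contrasted against baseline — with fixed effects and covariance components
set to that study's published estimates (G standard deviations
0.11/0.29/0.22 with correlations 0.75/0.64/0.49; E standard deviations
0.12/0.24/0.26 with correlations 0.68/0.64/0.64).  Covariate
distributions are not published, so the generator's choices are its own:
zBMI ~ N(0, 1) and income ~ categorical(middle 0.5, high 0.3, low 0.2).
Optional missingness is missing-completely-at-random per follow-up
occasion (baseline always kept so every subject remains in the sample);
the real cohort's missingness mechanism is unknown.

What the generator does *not* emulate: accelerometer measurement error and
minute-classification noise, non-Gaussian coordinate distributions,
informative dropout, school-level clustering, or serial correlation across
occasions.  Passing tests therefore certify the estimator and its
inferential machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Problem sizes used in the checks

The test-suite's simulation studies use: parameter recovery — 100
replicates at the full study size (241 × 5), checking fixed effects
against truth within 3 Monte-Carlo standard errors, variance-component
mean relative bias < 10%, and 95% Wald coverage inside [0.90, 0.99]; null
calibration — 500 replicates of 60 subjects × 5 occasions each for the
joint F test under null time effects (rejection within 3–7% at α = 0.05)
and for the df-6 LRT under diagonal truth (2–8%).  The calibration
replicates use a reduced subject count as a deliberately scaled-down
design; per-replicate information is smaller but the null distributions
being checked are the same.  Oracle comparisons use a 6-subject ×
3-occasion fixture where dense likelihood evaluation is exact and cheap.

## Known limitations

- One grouping level; no random slopes; no serial residual correlation;
  no heterogeneous E across occasions.  These are extension points.
- Denominator df are a counting approximation; small-sample F reference
  accuracy is not guaranteed to match moment-matching approximations.
- Zero parts are rejected, not replaced; data with structural or rounded
  zeros need pre-processing.
- AIC/BIC use the stacked-row count as n in the BIC penalty; other
  software may count subject-occasions or subjects, so compare information
  criteria only within this package.
- Percentile bootstrap intervals are first-order; no BCa correction.
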