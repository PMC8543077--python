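# Methods

## The problem

Two British birth cohorts, thirty years apart, rated young children's
behaviour with related but distinct maternal questionnaires.  Comparing the
*distribution* of the underlying socio-emotional skills across cohorts is
only meaningful if the items relate to the latent skills in the same way in
both cohorts — a property (measurement invariance) that must be tested, not
assumed.  The package implements the full chain: harmonised ordinal items →
polychoric moments → multiple-group ordinal factor models with an
invariance ladder → factor scores → inequality statistics → decomposition
of inequality changes → outcome regressions.  Because the cohort microdata
are restricted-access, a first-class synthetic generator reproduces the
statistical structure the analysis assumes, and every stage is validated
against it.

## Measurement model

Child *j* in group *c* (cohort × gender) has latent skills
θ_jc = (θ^EXT, θ^INT) ~ N(κ_c, Φ_c).  Each of the 11 items has a continuous
response propensity

    X*_ijc = ν_ic + λ_ic θ_jc(f(i)) + u_ijc,   u ~ N(0, ψ_ic),

with a congeneric pattern (items 1–6 load only on EXT, 7–11 only on INT),
and the observed ordinal code is produced by thresholds τ_ic (two for
3-category items, one for binary items).  All items are coded so higher =
better behaviour.

## Estimation (WLSMV)

Stage 1 estimates, per group, item thresholds (inverse-normal CDF of
cumulative proportions) and all pairwise polychoric correlations (two-step
ML with thresholds fixed, safeguarded Fisher scoring on ρ to |step| < 1e-10,
bisection fallback; bivariate-normal rectangle probabilities via Owen's T,
absolute accuracy ≈ 1e-14).  The full asymptotic covariance Γ of the stacked
(τ̂, ρ̂) vector is assembled from per-observation influence functions, with
the stage-2 influences corrected for threshold estimation.

Stage 2 minimises the diagonally weighted least squares discrepancy

    F(θ) = Σ_c n_c (s_c − σ_c(θ))' diag(Γ_c)⁻¹ (s_c − σ_c(θ)),

by trust-region-reflective least squares (finite-difference Jacobians of
the smooth implied-moment map; analytic Jacobian for the delta-configural
map; convergence: parameter tolerance 1e-12 and first-order optimality
below 1e-3·max(1, F), bound-aware so Heywood-boundary solutions count as
converged).  The full Γ is then used for mean-and-variance-adjusted
(Satterthwaite) test statistics — T_scaled = T·tr(M)/tr(M²), df =
tr(M)²/tr(M²) with M = (V − VJ(J'VJ)⁻¹J'V)Ω — and sandwich standard
errors.  A simulation check (200 replications) keeps reported SEs within
25% of the Monte-Carlo dispersion.

## The invariance ladder

Four nested models, identified per the categorical-measurement ladder:

1. **configural** — group-specific t, loadings, factor correlation.  Three
   interchangeable normalisations are implemented (delta: unit propensity
   variances; theta: unit error variances; anchored: reference loadings
   fixed at one with shared anchor thresholds).  They are verified to give
   identical fit to 1e-6.
2. **thresholds** — thresholds equated.  With ≤3 categories per item this
   is a reparameterisation of the configural model (intercepts, and scales
   of 3-category items, absorb the constraints in non-reference groups;
   binary items free only their intercept — freeing both would be
   unidentified).  Equal fit is asserted in tests.
3. **thresholds + loadings** — loadings also equated; factor covariances
   freed in non-reference groups (variance comparisons become meaningful).
   Scales of *all* items are freed in non-reference groups, since group
   differences in latent variance change every item's propensity variance.
4. **+ intercepts** — intercepts forced to zero everywhere; factor means
   freed in non-reference groups (mean comparisons become meaningful).

Free-parameter counts for four groups: 124, 124, 106, 79.

### Fit assessment

Large cohort samples make Δχ² reject trivial misfit, so the decision uses
approximate fit indices relative to the configural model: CFI, TLI, RMSEA
(with 90% CI), SRMR, McDonald's noncentrality index and Gamma-hat, all
computed from the scaled statistics.  Default rejection cutoffs (all
configurable, none hard-coded): ΔCFI ≤ −.010, ΔRMSEA ≥ .010 (the
categorical-data large-sample rule; the classic .015 rule is also carried),
ΔSRMR ≥ .010.  The scaled Δχ² (second-order-corrected) is reported
alongside for completeness.

**SRMR bias correction.**  The naive SRMR has a noise floor of order
√(p/n): with 296 moments at n ≈ 5000/group the configural SRMR is ≈ .015
even under perfect fit, which attenuates differences between nested models
and makes the Δ rules insensitive exactly where they are needed.  SRMR is
therefore reported with an exact first-order bias correction — each squared
residual is reduced by its fitted-residual sampling variance
diag((I−H)Ω(I−H)') — so the index estimates the population root mean
squared residual that the published cutoff rules refer to.  The uncorrected
variant is available via `bias_correct=False`.

The baseline (null) model for incremental indices is per-group independence
with free thresholds — the standard choice for ordinal moments.

## Factor scores

Scores are Empirical Bayes Modal: the posterior mode of θ given a child's
responses, the group's item parameters, and the group's N(κ_c, Φ_c) prior.
Group-specific intercepts and covariances are deliberately used because
intercept invariance fails: scores are comparable in spread, not in
cross-cohort location.  The ordinal-probit log-likelihood is log-concave in
θ, so a damped Newton iteration from the prior mean (vectorised over unique
response patterns) finds the global mode; a 0.01-step grid maximiser is the
test oracle.  Scores are reported in reference-group units (BCS males: mean
0, SD 1).  EBM scores are shrunken toward the prior mean; downstream
regression coefficients on scores are therefore attenuated relative to
structural coefficients on true skills, and tests compare against a
simulation oracle rather than the structural value.  No shrinkage
correction or plausible-value machinery is applied (a known limitation).

## Inequality statistics

Quantile gaps (90–10, 75–25, 50–10, 90–50) and variances per group, with
linear-interpolation sample quantiles (the convention matters at small n
and is fixed); stratified percentile bootstrap (default B = 1000; the
factor-estimation stage can be re-run per replicate via a flag, default
off); two-sample Kolmogorov–Smirnov tests (asymptotic p, exact below n=10);
and covariate gap tables normalised to a reference category, so only
within-group gradients are compared across cohorts.  Every statistic is
invariant to adding a constant to one group's scores — the location guard
that encodes the refusal to compare non-invariant means — and this is
enforced by test.

## RIF decomposition

Changes in a distributional statistic ν (quantile gap or variance) between
a source and a target group are decomposed with the two-stage reweighting
approach: a logit propensity of target membership builds odds weights
p/(1−p) (trimmed to [.01, .99], trim counts logged) that reweight the
source to the target covariate distribution; recentered-influence-function
regressions (RIF for quantile q_t: q_t + (t − 1{y≤q_t})/f̂(q_t), with a
Gaussian-kernel Silverman-bandwidth density, Epanechnikov configurable;
variance: (y−ȳ)²) then split

* ν_c − ν_s into **composition** ((X̄_c−X̄_s)'β_s, detailed per covariate)
  plus **specification error** (X̄_c'(β_c−β_s)), and
* ν_t − ν_c into **coefficient** (X̄_t'(β_t−β_c), detailed) plus
  **reweighting error** ((X̄_t−X̄_c)'β_c),

with all statistics evaluated as means of RIF values so the four-term
adding-up and the per-covariate detail sums are exact to machine precision.
Full-procedure bootstrap (resampling children, re-running reweighting, RIF
and regressions; default B = 500) supplies SEs and normal-approximation
p-values.  Note that the specification error genuinely picks up RIF
linearisation error: a large pure *location* shift contributes its squared
mean change to the variance statistic's specification error.  The
composition-only validation DGP therefore moves the spread (not the
location) through a covariate, where the variance RIF is exactly linear.

## Outcome regressions

Later outcomes are regressed by least squares on the two skill scores, an
optional cognitive score, and family-background covariates; binary outcomes
run as linear probability models to keep coefficient layouts uniform.  SEs
come from a bootstrap that re-runs the entire measurement stage per
replicate (default B = 1000); fitting several groups through one shared
bootstrap loop pairs the replicate draws, which is what the cross-cohort
coefficient-equality test (z on the paired-difference bootstrap SE, or a
centred percentile rule) relies on.  The cognitive score is a one-factor
minres fit on the Pearson correlations of the continuous cognitive
measures with Bartlett scoring, standardised *within* cohort — the
cognitive batteries share no items across cohorts, so this score is
intentionally not cross-cohort comparable.

## Synthetic cohorts

The generator draws covariates (Bernoulli and normal family-background
variables with per-cohort parameters matching the published summary
statistics: maternal age 25.9 vs 29.4, unmarried .05 vs .36, smoking .39 vs
.20, education .38 vs .57, and so on), then skills θ | covariates (normal
around a centred covariate-driven mean, so κ remains the marginal mean),
then propensities and ordinal codes, cognitive measures, and outcomes.
The default study-like configuration: cohort sizes 9545 and 5572 split by
gender; standardised loadings .50–.70; thresholds giving minority problem
prevalences; factor correlation .35; later-cohort factor SDs 20% (EXT) and
18% (INT) larger; intercept shifts of ±0.2 on four items (distracted and
tantrums worse, worried and unhappy better) in the later cohort only, so
threshold and loading invariance hold while intercept invariance fails;
covariate effects on skills signed and sized like the published
determinants regressions (≈ .01–.3 SD).  Where the source tables report no
latent-scale magnitude, values were chosen once as field-plausible and are
not calibrated to outputs.

What the generator does *not* emulate: the later cohort's stratified
oversampling design, attrition and item non-response, non-normal latent
skills, and the judgement-based item harmonisation itself.  Passing tests
therefore show the estimators are correct under the model's assumptions at
realistic sizes — not that the assumptions hold in the real cohorts.

## Simulation sizes used in the test suite

Oracle-equivalence checks run at n = 2000 (polychoric grid) and 100
children (EBM grid); recovery at 4 × 10,000; ladder operating
characteristics over 50 replications per arm at 5000/group; robust-test
size over 100 replications at 2 × 800; the two-step equality-test size over
100 replications of a reduced single-factor system (externalising items
only, two identical groups of 500, B = 100).  The single-factor reduction
avoids a small-sample artifact of the full miniature system: with three
items per factor at a few hundred children, the estimated factor
correlation occasionally hits its boundary, the two scores become
collinear, and individual regression coefficients explode — a pathology of
extreme miniaturisation, not of the method at study scale.

## Numerical choices and degenerate inputs

Correlations are constrained to (−0.9995, 0.9995); pairs at the bound are
flagged near-singular.  Items observed in a single category, pairs with all
mass in one row/column, empty groups, non-positive-definite factor
covariances, perfect propensity separation, collinear covariate sets and
constant outcomes are hard errors with named offenders.  Empty bivariate
cells simply contribute nothing to the polychoric likelihood — no
continuity correction, since smoothing would silently change test
statistics.  Bootstrap replicates that fail are dropped and counted, with
an error above a 1–5% failure share.  All randomness flows from explicit
seeds; one root seed is split per stage in the pipeline and the acceptance
script.
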