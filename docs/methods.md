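# Methods

## The model

`twinace` analyses a binary phenotype measured at two ages (labelled 3 and
7) in monozygotic (MZ) and dizygotic (DZ) twin pairs under the liability
threshold model: each person has a latent, standard-normal liability per
age, and the observed phenotype is 1 when liability exceeds a threshold
τ_age.  The threshold is tied to prevalence: τ = Φ⁻¹(1 − p).

Across the two ages, liability is decomposed with a bivariate Cholesky ACE
factor model.  Writing A, C, E for additive-genetic, shared-environment and
non-shared-environment factor scores,

    L₃ = a₁₁A₁ + c₁₁C₁ + e₁₁E₁ (+ b₃·PRS + β₃·male)
    L₇ = a₂₁A₁ + a₂₂A₂ + c₂₁C₁ + c₂₂C₂ + e₂₁E₁ + e₂₂E₂ (+ b₇·PRS + β₇·male)

A factors correlate 1 across MZ co-twins and 0.5 across DZ co-twins, C
factors correlate 1, E factors 0.  The optional polygenic score (PRS) is an
observed, standardized regressor; as an additive genotype score it is
shared exactly by MZ co-twins and correlates 0.5 in DZ pairs.  Liability is
standardized (unit variance per age), so squared paths are variance
proportions: heritability is a₁₁² at age 3 and a₂₁² + a₂₂² at age 7, and
the cross-age liability correlation decomposes additively as

    r_liab = a₁₁a₂₁ + c₁₁c₂₁ + e₁₁e₂₁ (+ b₃b₇),

with factor correlations rA = a₁₁a₂₁ / √(a₁₁²(a₂₁² + a₂₂²)) and the E
analogue.  The sex covariate is a liability mean shift for males (one
parameter per age), equivalent to sex-specific thresholds; it captures the
male excess in prevalence without touching the covariance structure.

## Likelihood and fitting

Fitting is raw-data maximum likelihood over pair response patterns.  A
pair's contribution is the rectangle probability of its observed pattern
under the implied 4×4 liability correlation matrix of its zygosity group,
with bounds (τ_eff, ∞) for affected and (−∞, τ_eff) for unaffected
entries; missing observations are marginalized out exactly by dropping
their dimension.  Pairs are collapsed to distinct (group, sex
configuration, response pattern) cells first, so one likelihood evaluation
costs one vectorized rectangle integration per (group, missingness mask)
rather than one per pair; twins within a pair are put in a canonical order
beforehand, which makes the likelihood exactly exchangeable in twin
labelling.  Pairs with genotype data are evaluated conditional on their
observed PRS values (Gaussian conditioning shifts the liability means and
shrinks the covariance); pairs without genotypes use the PRS-marginal
covariance, so partially genotyped cohorts are handled by marginalization.

Standardization is enforced structurally rather than by post-hoc
rescaling: e₁₁ and e₂₂ absorb the variance the free paths leave
(e₁₁ = √(1 − a₁₁² − c₁₁² − b₃²), analogously at age 7), so every interior
point of the parameter space satisfies unit liability variance exactly and
thresholds and paths are jointly identified, matching the ordinal-SEM
convention.  Diagonal Cholesky paths are bounded ≥ 0 for identification;
off-diagonal paths are sign-free.  The non-shared-environment variance has
a floor of 1e−4; when the optimizer pushes past it the variance is clamped
there and a smooth quadratic penalty is added — a hard infeasibility cliff
breaks finite-difference line searches, a soft wall does not, and the
penalty is inactive at any interior optimum.

Optimization uses L-BFGS-B with numerical gradients, starting from
Falconer method-of-moments values (A = 2(rMZ − rDZ), C = 2rDZ − rMZ,
E = 1 − rMZ) computed from pooled tetrachoric correlations, with
thresholds from sex-specific marginal prevalences.  Because this start is
already close to the optimum, the default is a single start; seeded
jittered restarts (up to five) run automatically if convergence fails, and
`n_starts` can force more.  Convergence requires the optimizer's relative
objective criterion (`ftol`, default 1e−11) or a gradient norm below
1e−5·max(1, |loglik|).

## Rectangle probabilities

One- and two-dimensional rectangles use exact special-function formulas
(the bivariate CDF by composite Gauss–Legendre quadrature on panels of
width ≤ 0.5, accurate to near machine precision).  Three- and
four-dimensional rectangles use separation-of-variables (sequential
conditioning on the Cholesky factor) integrated over a *fixed* scrambled
Sobol point set, vectorized across all bound sets that share a correlation
matrix.  The fixed point set makes likelihood values reproducible
run-to-run and the objective a smooth deterministic function of the
parameters, which quasi-Newton optimization needs.  At the default 8,192
points the absolute error is ~1e−7 for the well-conditioned matrices the
twin model produces; near-singular correlation matrices converge more
slowly (observed ~3e−5 at condition number ~1.5e4).  Model fitting uses
1,024 points by default (documented error well below the sampling noise of
any cohort considered here); `points` is exposed everywhere.

## Tetrachoric correlations

Tetrachoric estimation is two-step: thresholds fixed at the
marginal-prevalence quantiles, then a bracketed Brent search for the
correlation maximizing the multinomial likelihood of the 2×2 cells, on
[−1 + 1e−8, 1 − 1e−8] with tolerance 1e−10.  Perfect association (both
discordant or both concordant cells zero) returns a flagged boundary
estimate at ±(1 − 1e−8); if only some cells are zero, 0.5 is added to
every cell and flagged, leaving exact tables untouched.  Standard errors
come from the numerical curvature of the profile likelihood in ρ (they
ignore threshold uncertainty, which is negligible at registry sample
sizes).

## Hypothesis tests

Nested model comparisons use likelihood-ratio tests.  When the constraint
pins a variance component to its zero boundary (e.g. dropping the C
paths), the naive χ² p-value is conservative; the package reports it
together with a 50:50 χ²(df):χ²(df−1) mixture p-value and a boundary
flag.  Sex-limitation tests compare free group-specific tetrachoric
correlations (MZ-MM, MZ-FF, DZ-MM, DZ-FF, DZ-OS) against equality within
MZ (1 df) and across the three DZ groups (2 df); the DZ test includes
opposite-sex pairs and is therefore also sensitive to qualitative sex
differences (partly different genes acting in boys and girls).  PRS tests
are b₃ = b₇ (1 df) and common b = 0 (1 df); both are interior hypotheses
(slopes are sign-free), so the plain χ²(1) reference applies.  No
multiple-testing adjustment is applied; p-values are raw.

## Synthetic cohorts

The generator draws factor scores exactly as the path model prescribes and
is therefore also the round-trip oracle for the fitter.  Defaults describe
a registry-like cohort: 7,329 MZ pairs (sex split even, which registries
approximate), 7,177 same-sex DZ pairs (even MM/FF), 7,035 opposite-sex DZ
pairs; generating paths reproduce standardized components 0.796/0.157/0.046
(age 3) and 0.904/0/0.096 (age 7) with rA = 0.807 and rE = 0.934;
sex-specific prevalences 12.6% (boys) / 8.3% (girls) at age 3 and 10.3% /
7.0% at age 7, taken from a four-group-by-sex cross-tabulation of 15,213
children; per-observation missingness 0.406, completely at random, chosen
so ~35% of children are observed at both ages; genotyped fraction 0.155
with both members of a pair genotyped together.  Missingness is MCAR —
the simplest mechanism compatible with the MAR assumption the raw-data
likelihood needs; the generator does not emulate informative dropout,
zygosity misclassification, reporting error in the parental surveys, or
covariates such as breastfeeding or atopy.  Passing recovery tests
therefore show the estimator is consistent under the model's own
assumptions, not that those assumptions hold in registry data.

`SimulationConfig.scaled(f)` shrinks all group sizes by a common factor
for desk-scale runs; all other conditions stay put.

## Problem sizes used in the checks

Parameter-recovery checks fit 20 cohorts at the full default group sizes
(21,541 pairs each; one fit takes ~10 s after pattern collapsing).  Null
calibration of the PRS slope test uses 100 replicates of ~2,000-pair
cohorts; the DZ sex-equality calibration uses 200 such replicates.  The
Monte-Carlo cross-check of the rectangle integrator uses 100 random 4-D
specifications against 1e7 draws each.

## Design choices where the design was open

* The cross-age A contribution is a₂₁·a₁₁, parallel to the C and E terms;
  this is the only reading consistent with the reproduced decomposition.
* Thresholds are equated across twin 1/twin 2 and across zygosity groups
  (exchangeability); sex enters as the mean-shift covariate.
* Opposite-sex DZ pairs use genetic relatedness 0.5 by default; a config
  switch (`free_dzo_ra`) frees their genetic correlation for the
  qualitative sex-limitation variant.
* The PRS is treated as an observed regressor, not a latent factor; its
  cross-twin correlation in DZ pairs is fixed at 0.5, the expected sibling
  sharing of an additive score.
* The cross-age liability correlation is reported from the fitted model
  (sex-adjusted); the raw within-person tetrachoric is available from the
  same table machinery for comparison.
* Pairs with no observed phenotype are dropped with a logged count; they
  carry no likelihood information.

## Known limitations

Dominance (ADE) models, more than two ages, continuous phenotypes,
gene–environment interaction and scalar (variance-magnitude) sex
limitation are out of scope.  Standard errors for path coefficients are
not reported (tests are likelihood-based); tetrachoric SEs ignore
threshold uncertainty.  Rectangle probabilities are limited to dimension
four, which suffices for two ages.
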