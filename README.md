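# twinace

Bivariate liability-threshold ACE modelling for longitudinal twin data.

`twinace` is for behaviour-genetics and epidemiology researchers who have a
binary phenotype (e.g. parental-reported asthma-like symptoms) measured at
two ages in monozygotic (MZ) and dizygotic (DZ) twin pairs and want to know
how much of the variation — and how much of its *persistence* across ages —
is due to genes versus environment.

## The model

Each person has a latent standard-normal **liability** per age; the
phenotype is 1 when liability exceeds a threshold τ = Φ⁻¹(1 − prevalence).
Twin resemblance is summarized by **tetrachoric correlations** (the
correlation of co-twins' liabilities inferred from a 2×2 table), and the
liability is decomposed with a **Cholesky ACE** factor model:

    L₃ = a₁₁A₁ + c₁₁C₁ + e₁₁E₁
    L₇ = a₂₁A₁ + a₂₂A₂ + c₂₁C₁ + c₂₂C₂ + e₂₁E₁ + e₂₂E₂

where additive-genetic factors (A) correlate 1 in MZ and 0.5 in DZ pairs,
shared environment (C) correlates 1, and non-shared environment (E) is
individual.  With standardized liability, heritability is a₁₁² at age 3 and
a₂₁² + a₂₂² at age 7; the cross-age liability correlation decomposes as

    r_liab = a₁₁a₂₁ + c₁₁c₂₁ + e₁₁e₂₁,

and the genetic correlation across ages is
rA = a₁₁a₂₁ / √(a₁₁²(a₂₁² + a₂₂²)) (E analogous).  Optional extensions: a
standardized polygenic score as an observed regressor with age-specific
slopes b₃, b₇, and a male liability shift per age for sex differences in
prevalence.  Models are fitted to the raw pair data by full-information
maximum likelihood (multivariate-normal rectangle probabilities per
response pattern, missing observations marginalized), with pairs collapsed
to distinct patterns so registry-scale cohorts fit in seconds.

The package also provides Falconer method-of-moments estimates
(A = 2(rMZ − rDZ), C = 2rDZ − rMZ, E = 1 − rMZ), likelihood-ratio tests
(with boundary-aware mixture p-values), sex-limitation tests on
group-specific correlations, PRS slope tests, and a synthetic
registry-like cohort generator so the whole pipeline is testable without
access to registry data.

## Worked example

Simulate a registry-like cohort (~21,500 pairs; age-3 prevalence ≈ 10%,
age-7 ≈ 9%, male excess in cases, ~40% item missingness) and fit the
bivariate model with shared environment at age 3 only:

```bash
twinace simulate --seed 1 --out pairs.csv
twinace report pairs.csv --seed 1 --text --out report.json
```

which prints (abridged):

```
Tetrachoric correlations (cross-twin)
  MZ     age 3: rho 0.965 (se 0.007)  [n=2619]
  MZ     age 7: rho 0.907 (se 0.015)  [n=2581]
  DZ-SS  age 3: rho 0.612 (se 0.034)  [n=2532]
  DZ-SS  age 7: rho 0.496 (se 0.043)  [n=2439]
  DZ-OS  age 3: rho 0.560 (se 0.039)  [n=2457]
  DZ-OS  age 7: rho 0.446 (se 0.049)  [n=2432]
  within-person-3-7 ages 3-7: rho 0.775 (se 0.011)  [n=14983]

Model ACE-C3: loglik -13524.801, 9 free parameters, converged
  Standardized liability variance components
    age 3: A 0.812  C 0.154  E 0.034  PRS 0.000
    age 7: A 0.908  C 0.000  E 0.092  PRS 0.000
  Liability covariance ages 3-7: 0.771  (rA 0.846, rE 0.784)
    contributions  A 0.727  C 0.000  E 0.044
    proportions    A 0.943  C 0.000  E 0.057

Tests
  sex-equality-DZ-age3: chi2(2) = 2.089, p = 0.352
```

Read: MZ correlations far above DZ at both ages indicate strong genetic
influence — heritability ≈ 0.81 at age 3 and ≈ 0.91 at age 7, with shared
environment contributing only at age 3.  The cross-age liability
correlation (≈ 0.77 in this replicate, the *persistence* of the phenotype)
is almost entirely genetic: ~94% of it is carried by the A paths, with a
genetic correlation of ≈ 0.85 between the two ages.  The raw within-person
cross-age tetrachoric (0.775) and the model's sex-adjusted liability
correlation (0.771) agree closely, as they should.  The non-significant
sex-equality tests say the twin correlations do not differ between boys and
girls, i.e. the same factors act in both sexes.  The same quantities are available from
Python via `twinace.simulate_pairs`, `twinace.fit_ml`,
`twinace.derived_quantities` and friends, and `report.json` carries the
full-precision machine-readable report (schema in
`src/twinace/report_schema.json`).

The generating values behind the simulator's defaults are the reconstructed
components 0.796/0.157/0.046 (age 3) and 0.904/0/0.096 (age 7) with
rA = 0.807 and rE = 0.934, so the fit above is a round-trip check you can
rerun with any seed.

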