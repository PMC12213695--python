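# Methods

## The regression model

The exposure is a nine-part macronutrient composition — animal protein
(AP), vegetable protein (VP), simple sugars (SS), starch (ST), and the
fat fractions SFA, MUFA, LA, ALA and other PUFA — expressed as shares of
food energy and closed to sum to one. Compositions carry only relative
information, so the parts enter a regression through log-ratio
coordinates. We use the additive log-ratio (ALR) transform
ln(xⱼ/x_den) with starch as the default denominator, giving eight
coordinates per subject in the fixed order (AP, VP, SS, SFA, MUFA, LA,
ALA, PUFA)/ST.

The outcome is the three-level community state type (CST) grouping:
"I-II-V" (CSTs dominated by *L. crispatus*, *L. gasseri* or
*L. jensenii*; the reference level), "III" (*L. iners*-dominated) and
"IV" (polymicrobial/dysbiotic). Sub-CST labels (e.g. IV-B) collapse to
their major type. A multinomial logit links the ALR block, continuous
adjusters (total energy kcal/day, fiber g/day, alcohol AU/day with
1 AU = 10 g ethanol) and confounders (age, BMI, and binary marital
status and hormonal contraception; perceived-stress score optionally)
to the outcome. Fitting is full maximum likelihood by Newton iteration
(statsmodels MNLogit) with tolerance 1e-8 and at most 100 iterations;
standard errors come from the inverse observed information and Wald
p-values are two-sided. Rank-deficient designs are rejected with the
offending columns named (QR pivoting); apparent separation — divergent
slope coefficients or non-convergence — is flagged with a warning and
the coefficients are reported as-is, never truncated. No
multiple-testing correction is applied by default, matching the raw
p ≤ 0.05 convention of the analysis the package reproduces.

**Relative dominance.** The effect of "part j up, everything else
down" is read from two fits. Run 1 (denominator ST) yields the
coefficients of the eight other parts; run 2 (denominator AP)
contributes the starch coefficient via its ln(ST/AP) column. Because
any ALR basis spans the same log-contrast subspace, the two runs have
identical fitted probabilities and log-likelihood, and the run-2
ln(ST/AP) coefficient equals −Σ(run-1 compositional coefficients)
exactly; the implementation reproduces this to 1e-6 (coefficients) and
1e-8 (log-likelihood), which doubles as an internal correctness check.
The pivot balance √((D−1)/D)·ln(xₚ/g(others)) is provided and is
explanatorily equivalent: substituting it for a part's ALR column (with
any completion of the log-contrast space) leaves fitted values
unchanged, which a test verifies numerically.

Zeros are handled before transformation by multiplicative replacement:
zero parts are set to a small δ (default 1e-6, required to be below the
smallest observed non-zero part) and the remaining parts rescaled so
rows stay closed. Energy shares in realistic diets are strictly
positive, so this is a numerical safeguard rather than a modeling step.

## The synthetic cohort generator

The generator produces cohorts with exactly the structure the estimator
assumes, so recovery tests are well-specified.

- **Diet.** Logistic-normal: a multivariate normal on the eight ALR
  coordinates, mapped back to the simplex. Default means are
  ln(mean_j/mean_ST) of the cohort dietary descriptives (%E means: AP
  10.54, VP 5.78, SS 19.61, ST 28.02, SFA 12.08, MUFA 18.58, LA 4.79,
  ALA 0.43, PUFA 0.18 — these sum to ≈100). The default covariance is
  diagonal with var(ln xⱼ − ln ST) ≈ (sdⱼ/meanⱼ)² + (sd_ST/mean_ST)²
  by the delta method under independence — a deliberately simple
  dispersion model, fully overridable.
- **Outcome.** Labels are drawn from the multinomial logit with the
  2×(8+k) effect matrix over ALRs and covariates. Predictors are
  centered at their sample means and the intercepts set to the log-odds
  of the baseline prevalences (0.54, 0.292, 0.168), so those
  prevalences hold *at the covariate means*. Under the non-zero default
  effects the marginal prevalences therefore differ from the baseline
  (≈0.45/0.35/0.19 at large n — the expectation of a softmax is not the
  softmax of the expectation); with zero effects they match exactly,
  which is what the chi-squared calibration test checks. Default
  non-zero effects: −5.320 on ln(ALA/ST) for CST III, +2.702 on
  ln(AP/ST) and +1.570 per alcohol AU/day for CST IV.
- **Covariates.** Age, BMI, marital status, contraception, perceived
  stress, energy (clipped to the plausible 500–3500 kcal window), fiber
  and alcohol (zero-inflated lognormal: ≈8% abstainers) are generated
  independently of diet by default; their distribution parameters sit
  in the config.
- **Taxa.** Each group has a centroid over 15 taxa
  (*L. crispatus* 0.703/0.105/0.002 and *L. iners* 0.008/0.712/0.068
  across I-II-V / III / IV; CST IV concentrates the anaerobes, totaling
  ≈0.605). Per-subject relative abundances are
  Dirichlet(concentration × centroid) with default concentration 30,
  and counts are multinomial at a depth uniform on [6627, 20000] —
  the lower bound mirroring rarefaction to the shallowest library.
- **Metabolites.** Fourteen named metabolites load linearly (default
  loading 3, lactate 5) on the summed relative abundance of one of four
  taxa clusters (the *L. crispatus* group, the CST IV anaerobes, the
  "no-difference" taxa, and *L. iners* alone), plus a 0.2 baseline and
  Gaussian noise (sd 0.3), truncated at zero.
- **FFQ back-fill.** Item intakes are constructed from a bundled
  synthetic food-composition table with one dominant item per energy
  component (plus fiber and alcohol carriers), whose energies are exact
  Atwater sums (protein/carbohydrate 4, fat 9, alcohol 7 kcal/g).
  Deriving nutrients from these items reproduces each subject's
  composition to floating-point accuracy, giving a strict
  generator/processor round-trip oracle.

All randomness flows from a single config seed through spawned child
seeds; identical config and seed give byte-identical serialized
datasets.

**What the generator does not emulate.** Real vaginal profiles have
hundreds of taxa; with 15 taxa the absolute diversity indices are much
smaller than observed values (synthetic Shannon medians ≈1.5–3.2 bits
versus ≈4.4–6.7 in real data), so only their ordering across groups is
meaningful. Covariates are independent of diet unless configured
otherwise, so confounding strength is not represented by default. The
back-filled FFQ covers only nutrient-bearing food groups, so food-group
level statistics computed from it (e.g. the MEDI-LITE distribution,
mean ≈10 on synthetic data) are not calibrated to any observed score
distribution. Passing tests demonstrate correctness of the estimators
under the assumed model, not agreement with any particular real cohort.

## Supporting stages: choices that matter

- **Rarefaction** subsamples without replacement (multivariate
  hypergeometric), one draw per seed; samples below the target depth
  are dropped with a warning.
- **Shannon diversity** uses log base 2 (configurable); **Chao1** is
  the bias-corrected form S + F₁(F₁−1)/(2(F₂+1)).
- **CST assignment** maximizes Yue–Clayton θ = Σpq/(Σp²+Σq²−Σpq)
  against a centroid set. Centroids are an input artifact: a synthetic
  seven-centroid set (I, II, III, IV-A/B/C, V) is bundled for tests and
  demos, and `read_centroids` loads user-supplied TSV centroids. Ties
  break lexicographically and are reported. Profile taxa missing from
  the centroid list pool into "Other".
- **IndVal**: specificity A (share of between-group mean abundance) ×
  fidelity B (occurrence fraction), scaled to 0–100, best group
  reported; the permutation p uses the add-one correction
  (1+hits)/(1+n_perm), with exhaustive enumeration available for small
  designs.
- **PERMANOVA** uses Anderson's pseudo-F on squared distances with the
  same add-one permutation p. Bray–Curtis substitutes for
  phylogeny-dependent distances, which are out of scope.
- **PQN** forms quotients only over metabolites positive in both sample
  and reference (reference defaults to the first row, mirroring
  quantification in the first acquired sample) and divides by their
  median; samples sharing fewer than two positive metabolites are
  flagged and left unscaled. The procedure is idempotent and
  scale-equivariant to 1e-12.
- **Correlation screen**: tie-corrected Spearman with t-approximation
  p-values (the regime of ~100 subjects); exact permutation p is
  available for n ≤ 9. Taxa are prevalence-filtered at ≥1% in at least
  one sample (inclusive bound). Constant features are reported as
  undefined, never as zero correlation.
- **Cluster assembly**: taxa join the cluster of their significant
  indicator group (non-significant taxa form a residual
  "no-difference" cluster); metabolites and nutrients join the
  bacterial cluster with the largest mean significant positive rho,
  with multi-cluster positive ties annotated as shared rather than
  forced to one side.
- **MEDI-LITE** ships as data (YAML), not code: nine components scored
  0/1/2 — six positive food groups ascending, dairy and red/processed
  meat descending, and alcohol peaked at moderate intake (1 point below
  1.2 AU/day including abstainers, 2 points in 1.2–2.5, 0 above),
  following the published score's bands with serving thresholds
  converted to g/day. Every band is overridable.
- **Energy screen**: the plausibility interval [500, 3500] kcal/day is
  closed — the boundary values count as plausible.

## Problem sizes and calibration checks

The acceptance script and test suite run at desk scale: the default
cohort has 113 subjects; effect recovery uses one n=2000 cohort;
Wald-interval coverage uses 100 cohorts of n=500 (coverage required in
[0.90, 0.99] over the 1600 compositional intervals); null type-I error
uses 200 cohorts of n=400; the correlation-screen and PERMANOVA null
calibrations use 200 replicates each. Calibration bands are binomial
95% bands computed at the replicate count, because the several tests
inside one replicate share data and are positively correlated — a
pooled per-test band would be anti-conservative.

## Known limitations

- Spearman correlations on relative abundances ignore compositional
  constraints; spurious negative correlation among dominant taxa is
  inherent to the screen (as in the analysis it mirrors), and no
  partial-correlation or CLR-based correction is attempted.
- The univariate/multivariate distinction is configurable rather than
  fixed: `relative_dominance` takes any covariate frame, so both model
  layers are expressible and labeled by their inputs.
- The multinomial fit is unpenalized; quasi-complete separation in
  small strata is flagged, not resolved.
- Missing covariates are handled by complete-case exclusion inside the
  fit, with the number of dropped observations reported in a warning;
  no imputation is provided.
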