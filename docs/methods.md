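# Methods

This note documents the statistical machinery, the generative model behind
the synthetic cohorts, the numerical choices, and the limits of what the
test suite demonstrates.

## Model representation and estimation

Every model is a pair of maps from a named parameter vector to, per
zygosity group, (i) a mean structure and (ii) an implied covariance for the
stacked twin observation vector `(traits of twin 1, traits of twin 2)`.
Covariance structures provided:

- **Saturated** — free symmetric matrix per group; used as the comparison
  baseline and for assumption testing.  With complete data, free per-group
  means and no covariate, its ML solution is closed-form (sample means and
  ML covariances) and is computed directly.
- **Direct symmetric biometric** — free symmetric A (and optionally D or C)
  and E matrices; within-twin block A+D+C+E, cross-twin block
  r_α·A + r_δ·D + C with r_α ∈ {1, ½}, r_δ ∈ {1, ¼} keyed to zygosity.
  No positivity bounds: point estimates may leave the parameter space
  (flagged, never truncated), which keeps LRT statistics asymptotically
  calibrated. Variance components are constrained equal across the five
  groups; opposite-sex DZ pairs use r_α = ½ with no sex-limitation
  modelling — a deliberate simplification, listed under limitations.
- **Cholesky (path)** — lower-triangular X, Z with A = XXᵀ, E = ZZᵀ;
  PSD by construction; reflection invariance resolved by reporting
  diagonal paths ≥ 0.
- **Shared factor** — rank-1 + diagonal on one component, free symmetric on
  the other; nested in the direct-symmetric solution with Δdf = k(k−1)/2 − k.
- **One-factor CFA** and **independence** structures for individual-level
  indicator models and the CFI null baseline.

Means are `single` (one intercept per trait), `by_sex` (free per-sex
intercepts, shared across groups and twin order — the study's convention),
or `by_group` (saturated).  Age enters as a fixed per-trait slope on age
centered at the sample mean; a missing age on an otherwise observed twin is
treated as the mean age.

**FIML.** Each pair contributes the multivariate-normal log-density of its
observed sub-vector; rows are grouped by missing-data pattern so each
pattern's covariance sub-block is Cholesky-factorized once per likelihood
evaluation.  An implied covariance that is not positive definite yields a
large finite penalty graded by its most negative eigenvalue, so the
optimizer can back out rather than crash.

**Optimization.** L-BFGS-B with 2-point numerical gradients on the
unconstrained space, followed by a restart polish; if the quasi-Newton pass
reports failure and the problem has ≤ 20 free parameters, a Nelder–Mead
fallback runs from the best point (this matters only near singular optima,
e.g. within-pair correlations approaching 1).  Start values are
method-of-moments: pooled within-twin and cross-twin sample blocks, cross
terms shrunk 10 % toward zero, diagonals floored at a fraction of the
phenotypic variance.  Nested fits are warm-started from the parent's
solution; if a nested fit nonetheless beats its parent (a sign the parent
under-converged), the parent is refit from the nested solution before the
LRT, so the nesting inequality holds at the reported optima.  Convergence
failures are flagged on the result object, never silently accepted.

**Constraints.** Fixed parameters and equality ties are resolved by a
union-find parameter map; dropped components, zeroed cross-paths, pooled
covariances and cross-group equality tests are all expressed this way, so
every nested model is literally the parent model with a restricted map.

**Uncertainty.** Standard errors come from the inverse observed information
with the Hessian computed by central finite differences (relative step
1e-4).  Derived quantities — heritabilities, standardized components,
genetic correlations — get delta-method intervals; twin correlations get
Fisher-z intervals on complete-pair counts.  Wald intervals were chosen for
determinism; coverage is verified by simulation (0.95 ± 0.02 over 400
replicates at n = 1000 pairs).

**Fit statistics.** AIC = 2k − 2 lnL̂.  BIC defaults to the Schwarz form
k·ln(N individuals); a literal k·ln(k) variant is selectable for
comparison with sources that print it.  CFI uses likelihood-ratio
chi-squares against the saturated model, with the independence model (free
means and variances per group) as the null baseline; the baseline is
admissible whenever its likelihood does not exceed the model's — in
multigroup settings a constrained structured model need not contain the
per-group independence model parametrically, so admissibility is checked
on likelihoods, not parameter counts.  SRMR standardizes residual
covariances (diagonal included) by the saturated variances per group and
combines groups by a pair-count-weighted root mean square.

## Analysis pipeline conventions

- Saturated assumption tests constrain, in order: means and variances equal
  across twin order (mean equality skipped inside opposite-sex pairs, whose
  slots differ by sex), across zygosity groups (means within sex), then
  across sex.  Each level is compared to its predecessor by LRT at the
  study-wide α = 0.007 (configurable).
- Twin correlations come from the zygosity-constrained saturated model with
  covariances pooled within MZ and within DZ classes (per-group extraction
  available).
- Family selection: ADE iff r_MZ > 2·r_DZ, ACE otherwise, ties to ACE
  (at equality both C and D are zero-identified).
- Multivariate fits standardize traits (z-scores on pooled individual-level
  moments) before the Cholesky stage, matching the reported path scale; the
  facet-level distinct/shared solutions run on the raw score scale.
- The Cholesky trait order is fixed to (perception, general reward, music
  reward) so that the shared components are regressed out of music reward;
  any order can be supplied for sensitivity analysis.
- The six-variate extension reuses the distinct-factor machinery with a
  perception or general-reward anchor; equality tests constrain
  *covariances* (an option the field sometimes phrases as correlation
  contrasts — correlations are reported alongside for interpretation).

## Synthetic cohorts

The generator draws each group's pairs from a multivariate normal with the
model-implied (or directly supplied) 2k×2k twin covariance, with means
M_sex + B_age·(age − mean age) and a shared age per pair drawn from
Normal(51, 8) truncated to [37, 64] years.  Defaults mirror the study
conditions: five sex-by-zygosity strata with complete-pair counts
(MZ women 659, MZ men 400, DZ women 386, DZ men 268, DZ opposite-sex 592)
and singletons added to reach the per-group individual counts; sex means
76.26 (women) and 71.20 (men) on the 20–100 questionnaire scale with a
sex-constrained SD of 13.72; age slope −0.06 per year; generative
heritability 0.54.  Because the published record does not state how many
singletons carry phenotype data, singleton counts are free configuration
with the individual-minus-paired difference as default.

Three calibrated configurations drive recovery experiments:

1. **Univariate** — explicit twin covariances with within-pair correlations
   0.55 (MZ) and 0.24 (DZ) on a standardized trait.
2. **Trivariate** — Cholesky paths λ_A = (0.707, 0·, 0.592; 0.255, 0.312,
   0.615) and λ_E = (0.707, 0·, 0.806; 0, 0.141, 0.663), calibrated so the
   third trait has total h² = 0.54, adjusted h² = 0.38, 70 % of its genetic
   variance unique and 12 %/18 % shared with traits 1/2.  The implied
   trait-1 and trait-2 heritabilities (0.50 and 0.35) are a calibration
   choice — the published record does not report them — and the target
   quantities are invariant to that choice because they depend only on the
   paths into trait 3.
3. **Facet-level** — 10×10 MZ and DZ twin covariances reconstructed from
   the published facet SDs (3.47, 3.29, 3.85, 3.61, 3.58), phenotypic
   correlations and MZ/DZ twin correlations; both matrices are positive
   definite as transcribed (a nearest-PSD projection with warning exists
   for perturbed inputs).

Item-level questionnaire responses are generated by allocating the target
sum above the item floor uniformly at random across items (multivariate
hypergeometric over remaining capacity); only sums are analysed downstream,
so any allocation is statistically equivalent.  Reverse-coded items are
stored in raw orientation; which two items are reverse-coded is
configuration (default indices 2 and 11) — every statistic depends only on
the count.

**What the generator does not emulate.** Phenotypes are multivariate
normal, whereas real questionnaire sums are discrete, bounded and mildly
skewed (an optional sinh-arcsinh skewing transform exists, off by default,
matching the normal-theory ML analysis); missingness is MCAR although FIML
only requires MAR; there is no sex-limitation structure, no
gene–environment interaction, no assortative mating and no participation
bias.  Passing recovery tests therefore demonstrate correctness of the
estimators under the stated model, not robustness of the scientific
conclusions to violations of CTD assumptions.

## Problem sizes and determinism

Recovery experiments in `scripts/acceptance.py` run 20 seeded replicates at
the pooled study size (1059 MZ + 1246 DZ complete pairs); the test suite
uses 2–4 replicates at the same size for the headline checks and hundreds
of replicates at smaller sizes for calibration properties (LRT type-I
error, CI coverage).  All randomness flows through numpy `SeedSequence`
spawns of the user seed; fixed seeds reproduce cohorts bit-identically, and
the pipeline writes byte-identical reports on rerun.

## Known limitations

- No robust (sandwich/scaled) test statistics; normal-theory ML only.
- No ordinal/threshold models — raw sum scores are treated as continuous.
- No sex-limitation (scalar or non-scalar) models: opposite-sex pairs
  share the common r_α = ½ structure.
- No common-pathway (latent phenotype) model; the shared-factor solutions
  are the hybrid independent-pathway variants.
- E cannot be split into inter- and intra-individual parts without
  repeated measures.
- Wald/delta intervals can be inaccurate near parameter-space boundaries;
  a profile-likelihood alternative is not implemented.
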