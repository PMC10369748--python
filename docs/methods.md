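# Methods

## The problem

A covariate can be "damned if you do, damned if you don't": adjusting the
association models for it induces collider bias, while not adjusting leaves a
confounding or pleiotropy channel open. The canonical instance is a genotyping
batch assigned on the basis of phenotypes (e.g. smoking/lung function), which
makes the batch indicator simultaneously a collider between the genetic score
and outcome confounders and a carrier of instrument effects to the outcome.
`mviv` implements (i) a structural simulator for this situation, (ii) the GWAS
and instrument-processing machinery of a two-sample Mendelian randomisation
(MR) analysis, and (iii) the univariable and multivariable summary-data
estimator suite, so that the mitigation — multivariable instrumental
variables, which estimates the exposure's direct effect conditional on the
covariate — can be studied end to end.

## Structural model

With m variants (the first k instrumenting the exposure), allele frequencies
p_j ~ N(maf_mean, maf_sd²) clipped to (0.01, 0.99), dosages
SNP_j ~ Binomial(2, p_j), confounders C₁, C₂ ~ N(0,1), and per-variant
effects β_j, γ_j ~ N(snp_effect_mean, snp_effect_sd²):

    E = a₁·C₁ + Σ_{j≤k} β_j·SNP_j + ε₁
    P = a₂·C₂ + G_P + ε₂
    Y = θ·E + c₁·C₁ + c₂·C₂ + b·P + ε₃,   ε ~ N(0, noise_sd²)

Defaults: m = 100, k = 50, all structural coefficients 1, unit noise,
n = 250,000 per sample, three non-overlapping samples. The clipping of the
allele-frequency draws is the minimal fix for a normal distribution that can
stray outside [0,1]; the clip bounds are recorded with the cohort. Effects
and frequencies are drawn once per replicate and shared across the three
samples (they genotype the same variants); redrawing them each replicate
propagates effect-size uncertainty into the Monte-Carlo SE.

### The two covariate structures

`structure_variant` controls G_P, the covariate's genetic component:

* **`printed`** — G_P = Σ_{j>k} γ_j·SNP_j. The covariate has its own,
  disjoint instrument set. The exposure's instruments then have no path to
  the outcome other than through E, and no association with P, so *neither*
  univariable strategy is structurally biased: the covariate is a pure
  collider that nothing in the analysis conditions on a parent of.
* **`pleiotropic`** (default) — G_P = Σ_{j≤k} β_j·SNP_j + Σ_{j>k} γ_j·SNP_j.
  The exposure's genetic score itself feeds the covariate — a single genetic
  liability node with arrows to both exposure and covariate — in addition to
  the covariate's own instrument set. This makes the covariate both
  pleiotropic (instruments reach Y through P) and a collider (conditioning
  on P opens score ↔ C₂ → Y).

The pleiotropic structure is the default because it is the one in which the
adjustment dilemma actually exists, and the three-strategy bias pattern it
produces is sharp. Analytically, with shared liability the unadjusted
univariable IVW slope doubles (each instrument's outcome association is
β_j + β_j), giving bias ≈ +1; adjustment flips the bias negative (≈ −0.44 at
the default coefficients) through the collider path; and the multivariable
regression of B_y on (B_x, B_p) admits an exact representation
B_y = 1·B_x + const·B_p, so its exposure coefficient is centred on the truth
up to finite-sample attenuation. A variant of the pleiotropic structure with
*independently redrawn* effects on the shared set was considered and
rejected: it caps the unadjusted bias at E[βγ]/E[β²] ≈ +0.8 and produces a
markedly weaker collider bias, inconsistent with the bias pattern the default
is designed to exhibit. Under `printed` the package asserts the absence of
structural bias rather than its presence.

### What the simulator does not model

No linkage disequilibrium (variants are independent; the LD-aware clumping
path is exercised through explicit r² matrices instead), no binary/liability
outcomes (everything is Gaussian; "log-odds scale" outcomes in the applied
pipeline are taken as-is), no sample overlap, no population structure, no
genotyping error. Passing simulation tests therefore demonstrates estimator
behaviour under the structural mechanism, not robustness to those real-data
features.

## GWAS stage

Per-variant simple OLS of trait on dosage, optionally adjusted for the
covariate. Adjustment is computed by residualising trait and dosages on the
covariate (Frisch–Waugh), which reproduces the multi-column OLS coefficient
and its homoscedastic t-based standard error exactly; tests assert agreement
with an independent OLS implementation to 1e-8. SEs are the classical
(non-robust) OLS errors — the generating process is homoscedastic Gaussian
and this matches standard GWAS software at these sample sizes. Monomorphic
variants yield flagged missing records and are excluded downstream. There is
no default minor-allele-frequency filter (configurable).

## Instrument processing

Stage order: **select → FIQT → clump → standardise → harmonise**. Selection
must precede clumping; whether the winner's-curse correction belongs before
or after clumping is not determined by convention, so it is a configuration
switch (`fiqt_before_clump`, default true — with independent variants the
order is immaterial).

* **Selection** — keep p < threshold (default 5e-8), order preserved.
* **FIQT** — z → sign(z)·Φ⁻¹(1 − p_BH/2)·, β' = z'·se, SE unchanged, where
  p_BH is the Benjamini–Hochberg adjustment of the two-sided p. BH (not
  Bonferroni) follows the transform's construction. All p arithmetic is in
  natural-log space (`norm.logsf`, `ndtri_exp`) so |z| ≈ 40+ does not
  underflow; p_BH = 1 maps to z' = 0; an exactly-zero p keeps its z. Output
  p-values are recomputed from z' (≡ p_BH), keeping beta/se/p mutually
  consistent.
* **Clumping** — greedy: sort by ascending p, ties broken by ascending
  position then lexicographic id (determinism); keep the best remaining
  variant, discard same-chromosome variants within the window whose r² with
  it meets the threshold. Defaults r² = 0.001, window 10,000 kb. The LD
  provider is an interface; the identity provider (r² = 0 off-diagonal, for
  independent variants) and an explicit-matrix provider ship.
* **Standardisation** — divide beta and SE by a constant (z and p
  invariant). The constant is dataset-specific (0.6940093 for the published
  lifetime-smoking score), so the library default is *off*.
* **Harmonisation** — inner join on variant id; swapped or strand-flipped
  allele pairs are folded to the exposure's orientation (beta negated, EAF
  reflected as needed). Palindromic (A/T, G/C) variants carry no strand
  information; orientation is inferred from allele frequency only when both
  tables' EAFs lie outside the ambiguity band [0.42, 0.58] (same side ⇒
  aligned, opposite sides ⇒ flip), otherwise the variant is removed. The
  band is the conventional default of the dominant two-sample MR tooling and
  is configurable. Every drop is counted in the provenance
  (`not_significant`, `clumped`, `palindromic_unresolvable`,
  `allele_mismatch`, `missing_in_outcome`).

## Estimators

All weighted regressions use weights 1/se_y² and report normal-quantile 95%
intervals (estimate ∓ 1.96·se).

* **IVW**: intercept-free WLS, closed form Σw·b_x·b_y / Σw·b_x²;
  algebraically identical to the inverse-variance meta-analysis of the Wald
  ratios b_y/b_x. SEs carry a multiplicative overdispersion factor
  max(1, Q/(n−1)) — the "random effects, floored" convention of the dominant
  MR tooling; the source analyses do not state fixed vs random, so this is a
  documented default, not a claim of equality.
* **MR-Egger**: the same regression with an intercept after orienting all
  b_x ≥ 0 (the paired b_y flips sign), slope = causal estimate, intercept =
  directional pleiotropy; overdispersion floor max(1, RSS/(n−2)).
* **Weighted median**: order the ratios, form midpoint cumulative normalised
  weights (cum(w) − w/2), linearly interpolate the 50% crossing. SE by
  parametric bootstrap (default 1000 draws, seeded) of all betas from their
  sampling normals.
* **Weighted mode**: Gaussian kernel density over the ratios with weights
  normalised inverse variance; bandwidth = factor × 0.9·min(sd, 1.4826·MAD)
  ·n^(−1/5) (modified Silverman on a robust scale); argmax on a 10,000-point
  grid over the ratio range padded by three bandwidths; bootstrap SE. As the
  bandwidth grows the argmax tends to the weighted mean (checked
  numerically).
* **Wald ratio SEs** are first order, se_y/|b_x| — adequate for the strong
  instruments in all in-scope uses; no second-order term.
* **Multivariable IVW/Egger**: WLS of b_y on the exposure-beta matrix
  (no intercept / intercept after orienting on the first exposure), one
  result per exposure, shared multivariable Q, overdispersion floored at 1
  with denominator n − (fitted columns). An identically-zero exposure column
  is treated as carrying no information — coefficient 0, infinite SE — which
  makes the multivariable estimators reduce *exactly* to their univariable
  counterparts (a property test); genuine collinearity (condition number of
  the weighted design > 1e8) raises an error naming the condition number.
* **Multivariable median/mode**: b_y and the target exposure's betas are
  weighted-residualised on the other exposure columns; the univariable
  median/mode machinery then runs on the resulting conditional ratios (SE
  se_y/|residual b_x|). This residualisation construction is an
  approximation to the published multivariable mode estimator, differing in
  detail; its correctness anchor is the exact reduction to the univariable
  estimator when the other column is null and exact recovery on noiseless
  linear data.
* **Conditional F**: weighted-regress the target exposure's betas on the
  other exposures' betas (weights 1/se_target²), form Q of the residuals
  against zero, divide by n − (number of regressors). With one exposure this
  reduces to the mean univariable F, mean((b_x/se_x)²) — the documented
  degenerate convention; collinear exposure columns give ≈ 0.

## Simulation study runner

Sample 1 → exposure GWAS (B_x), sample 2 → covariate GWAS (B_p, never
self-adjusted), sample 3 → outcome GWAS (B_y). The three canonical
strategies: `uv_adjusted` (adjusted models, exposure variants, IVW),
`uv_unadjusted` (unadjusted models, exposure variants, IVW), `mv_adjusted`
(adjusted models, all variants, multivariable IVW). Instrument sets are the
known causal index sets; a significance screen is available as a sensitivity
option (`screen_p`). Bias is estimate − true effect; the report carries mean
bias, MC SE = sd/√reps, quantiles, the full config echo and the master seed.
Per-replicate seeds are spawned from the master seed before dispatch, so
results are invariant to the worker count. Because the simulated samples are
variant-aligned by construction, the runner assembles the harmonised set
directly rather than routing through allele harmonisation.

## Problem sizes used by tests and the acceptance script

The headline comparison is run at desk scale: 100 replicates of three
50,000-individual samples (the full-scale 1000 × 250,000 configuration is a
single flag change and takes a few hours on one core). At 50,000 the
structural biases are within a few thousandths of their asymptotic values;
the remaining finite-sample attenuation (ratio of beta-estimation error
variance to signal variance, ≈ 1%) is far smaller than the effects under
study. The `printed`-variant null check runs at n = 100,000 so that this
attenuation (< 0.004) sits below Monte-Carlo resolution of its zero-bias
assertion.

## Known limitations

* The fixture's winner's curse is a fixed multiplicative inflation of a
  documented subset of significant hits — convenient for exact-count tests,
  but not the selection-on-noise mechanism FIQT models, so FIQT only
  partially corrects it (and is tested for improvement, not elimination).
* Only two exposures (one exposure + one covariate) are supported in the
  harmonised container and multivariable estimators.
* The applied pipeline accepts log-odds-scale outcome statistics as-is; no
  binary-trait scale conversion is attempted.
* No reference-panel LD estimation; LD enters only through the provider
  interface.
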