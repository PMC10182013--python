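# Methods

## Design

The package implements a two-sample summary-statistics Mendelian
randomization analysis in which genetic variants strongly and
independently predicting a standardized exposure (basal metabolic rate,
in SD units of a rank-inverse-normalized phenotype) instrument its causal
effect on lifespan proxies. Two outcome families are supported: parental
attained age expressed as rank-normalized martingale residuals of a Cox
model (a *positive* coefficient encodes *reduced* attained age), and
survival to old-age percentiles on the log-odds scale. The analysis plan
is sex-stratified throughout (men's instruments against father's attained
age, women's against mother's), with a z-test for the sex difference and
a fixed-effect pool of the sex-specific years-of-life-lost estimates.

## Instrument selection

Variants are filtered in a fixed order — non-biallelic, rare
(MAF < 0.01), Hardy–Weinberg failure (chi-squared p < 0.05), sub-
genome-wide-significant (p ≥ 5×10⁻⁸; the boundary value is excluded) —
each variant counted against the first stage it fails so the selection
report partitions the input exactly. Biallelic flags and HWE p-values
require genotype-level information and are caller-supplied; when absent
those filters pass with a logged warning. LD clumping is greedy: the
remaining variant with the smallest p-value (ties by lexicographic
variant id, for determinism) indexes a clump and removes everything with
r² ≥ 0.001 against it. The confounder screen flags instruments associated
with any supplied confounder trait at p < 0.05/(J·T); flagged instruments
are *reported*, not removed — exclusion is a sensitivity analysis run by
the pipeline as a second instrument set.

## Harmonization

The exposure table is the reference orientation. Outcome rows with
swapped allele labels are reflected (β := −β, EAF := 1−EAF); rows
matching only after A↔T/C↔G complementation are treated as opposite-
strand reports. For palindromic variants (A/T, C/G) the letters carry no
strand information, so retention is governed by the exposure effect-
allele frequency: kept only when EAF ≤ 0.45 or ≥ 0.55. When the outcome
reports a frequency it must fall on the side of 0.5 implied by its label
(after accounting for a label swap); an inconsistent side is dropped as
ambiguous rather than silently re-oriented. When the outcome frequency is
missing, a palindromic variant passing the exposure window is retained by
label orientation with a logged warning — the frequency window is the
only stated criterion, and fabricating a frequency would silently change
the decision.

## Estimators

All pooled estimators consume harmonized instruments
(b̂x, σx, b̂y, σy); p-values are two-sided normal and CIs are ±1.96 SE.

- **IVW-MRE.** Zero-intercept WLS of b̂y on b̂x with weights 1/σy²
  (algebraically the inverse-variance pool of Wald ratios). Cochran's Q
  uses ratio weights b̂x²/σy²; the multiplicative overdispersion
  φ = max(1, Q/(J−1)) is floored at 1 so the random-effects SE never
  undercuts the fixed-effect SE.
- **Weighted median.** Ratios ordered with normalized weights, cumulative
  midpoint ranks S_j = Σ_{k≤j} w_k − w_j/2, linear interpolation at 0.5.
  The SE is the SD of the estimate over n_boot (default 1000) parametric
  resamples θ*_j ~ N(θ_j, σy_j/|b̂x_j|) at an explicit seed; the bootstrap
  count and seed are part of the reproducibility contract because the SE
  is count- and seed-sensitive in the third decimal.
- **MR-Egger.** Instruments are pre-oriented so every b̂x ≥ 0 (the
  intercept test is orientation-dependent; a fixed convention is
  required). Weighted regression with intercept; SEs scaled by
  √max(1, RSS_w/(J−2)). I²GX = max(0, (Q_GX−(J−1))/Q_GX) with Q_GX the
  1/σx²-weighted dispersion of |b̂x|, so it is orientation-invariant.
  An all-equal b̂x design is rejected as unidentifiable.
- **MR-PRESSO.** Observed statistic: Σ_j (b̂y_j − θ̂₍₋ⱼ₎ b̂x_j)²/σy_j²
  with leave-one-out IVW slopes. The null is rebuilt by n_sim (default
  10,000) parametric redraws of both sides; the global and per-variant
  p-values use the add-one Monte-Carlo estimator (k+1)/(n_sim+1) — a
  plain tail proportion returns exactly zero whenever the observed
  residual exceeds every simulated one, which at n_sim ≪ J/α flags clean
  variants spuriously. Per-variant p-values are Bonferroni-adjusted by J;
  outliers (adjusted p < 0.05) are removed and IVW-MRE recomputed. The
  distortion p compares the observed estimate shift against shifts from
  removing random same-size subsets.
- **MR-RAPS** (simple overdispersed form). Coordinate-descent
  maximization of the profile likelihood with per-variant variance
  σy² + θ²σx² + τ², τ² ≥ 0, convergence when successive (θ, τ²) move by
  < 1e−10 (at most 200 sweeps, non-convergence raised with the last
  iterate); SE from the observed information. The θ²σx² term carries the
  exposure measurement error that IVW ignores. A robust (Huber) loss is
  deliberately not enabled by default; the simple squared-error form with
  normal overdispersion is the variant specified for this analysis.

## Reporting scales

Years of life lost = martingale β × 2.2869 (father) or 2.5863 (mother)
× 10. Both factors are exposed as parameters for other cohorts but
default to these established approximations. Log-odds estimates and CI
bounds are exponentiated to odds ratios. The sex z-test is signed women −
men, so a positive z means a stronger effect in women. Cross-sex pooling
is fixed-effect: two strata cannot support a random-effects variance.

## Power

Two-sided power uses the normal approximation with non-centrality
|effect|·√(n·r²)/SD, where n is the outcome sample size and r² the total
exposure variance explained — the standard approximation that the
effective MR sample size is n·r². The detectable effect inverts the
(strictly monotone) power curve by bisection to 1e−8.

## Synthetic data generator

The generator emulates the two-sample structure at the study's design
magnitudes, which are its defaults: J = 178 independent instruments,
total r² = 0.065, exposure GWAS n = 166,000 (a sex-specific stratum of a
~360k biobank GWAS), outcome GWAS n = 415,311, causal slope 0.05 on the
martingale scale. Per-variant MAFs are uniform on (0.05, 0.5); true
instrument strengths are drawn as 30 + Exp(32) (mimicking a
genome-wide-significance floor near F = 30 with an exponential tail) and
rescaled so Σ b²·2·maf·(1−maf) equals the target r²; with the default
sample sizes this yields a mean F near 61 and I²GX ≈ 0.82. SEs follow the
single-variant regression approximation 1/√(2·maf·(1−maf)·n) for
standardized traits. Observed effects are b̂x ~ N(bx, σx) and
b̂y ~ N(θ·bx + α, σy).

Pleiotropy models: `balanced` (α ~ N(0, σα²)), `directional` (α drawn
with nonzero mean *in the exposure-increasing orientation* and presented
as sign(bx)·α — with the generator's random effect-allele orientation an
orientation-free constant would be symmetric and induce no directional
bias), and `outliers` (a fixed count of variants displaced by
±magnitude·σy). |α| is drawn independently of |bx|, so InSIDE holds by
construction. Allele labels plant palindromic pairs, label swaps and
strand flips that harmonization must undo; instruments are generated
LD-free (the analysis operates post-clumping), and LD matrices for clump
testing are separate block-diagonal fixtures.

What the generator does **not** emulate: linkage disequilibrium between
instruments, winner's-curse selection (observed exposure effects are not
conditioned on crossing the significance threshold, so the *observed* F
range extends below the selected-GWAS floor of ~30 even though true
strengths are floored there — this keeps the estimator-recovery tests
free of selection bias), sample overlap between exposure and outcome
GWASs, population stratification, and survival/selection mechanisms.
Passing tests therefore demonstrate correctness of the estimators under
their stated sampling model, not robustness to those real-data
complications.

## Known finite-strength properties the tests document

Two deliberate honest findings, verified by the simulation suite:

- **MR-Egger regression dilution.** At the study's instrument strength
  (I²GX ≈ 0.82–0.85) the Egger slope attenuates by approximately the
  factor I²GX (measured 0.0425 for a true 0.05), and a small positive
  leak appears in the intercept. The dilution-corrected slope recovers
  the truth, and both slope and intercept are unbiased when the exposure
  GWAS is large enough that I²GX ≈ 1 (the estimator's no-measurement-
  error assumption). This mirrors the standard caution against
  interpreting Egger estimates at I²GX < 0.9.
- **Weighted-median quantile bias under one-sided pleiotropy.** With 40%
  of instruments carrying a common positive pleiotropic effect, the
  weighted median converges to the 0.5/0.6 quantile of the valid ratio
  distribution — a bounded bias of roughly Φ⁻¹(0.83) times the effective
  ratio SE (≈ +0.07 at study scale), an order of magnitude smaller than
  the IVW contamination (≈ +1.2) but not zero. The estimator's robustness
  guarantee is *bounded* bias at finite instrument strength; exact
  unbiasedness holds only as instrument strength grows.

## Problem sizes

The simulation suites run at the study magnitudes with replicate counts
chosen for stable Monte-Carlo tolerances: 500 replicates for parameter
recovery, 1000 for null calibration, 300 for the pleiotropy studies, and
50 seeds × 2000 simulations for MR-PRESSO recall (the per-analysis
default remains 10,000 simulations). The end-to-end fixture mirrors the
study shape exactly — 178/180 instruments per stratum, with 16/19
planted confounder-flagged instruments — and its MAFs stay below 0.45 so
no palindromic instrument falls in the ambiguous window, making the
harmonized counts deterministic.
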