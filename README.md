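# mrlifespan

Sex-specific two-sample Mendelian randomization (MR) of basal metabolic
rate (BMR) on lifespan proxies — parental attained age (rank-normalized
martingale residuals, converted to years of life lost) and survival to
old age (log odds ratios).

## Who this is for

Epidemiologists and statistical geneticists who want a tested, scriptable
implementation of the full summary-statistics MR workflow: instrument
selection (biallelic / MAF / Hardy–Weinberg / genome-wide-significance
filters, greedy LD clumping at r² < 0.001, a Bonferroni confounder
screen), allele harmonization with the palindromic effect-allele-frequency
rule, five pooled estimators with pleiotropy diagnostics, conversion to
interpretable lifespan scales, sex-difference testing, and post hoc power.
A synthetic summary-statistics generator reproduces the statistical
structure of the real data sources so every stage is testable without any
data download.

## The statistics

For instrument *j* with exposure association $\hat\beta_{Xj}$ (SE
$\sigma_{Xj}$) and outcome association $\hat\beta_{Yj}$ (SE
$\sigma_{Yj}$), the Wald ratio is
$\hat\theta_j = \hat\beta_{Yj}/\hat\beta_{Xj}$ with first-order (Fieller
first-term) SE $\sigma_{Yj}/|\hat\beta_{Xj}|$. The estimators:

- **IVW, multiplicative random effects** (primary): the zero-intercept
  weighted regression
  $\hat\theta = \sum_j w_j \hat\beta_{Xj}\hat\beta_{Yj} \big/ \sum_j w_j \hat\beta_{Xj}^2$
  with $w_j = 1/\sigma_{Yj}^2$; the SE is inflated by
  $\sqrt{\max(1,\, Q/(J-1))}$ with $Q$ Cochran's heterogeneity statistic,
  so the random-effects SE never undercuts the fixed-effect SE.
- **Weighted median**: the Wald-ratio value at 50% of cumulative
  inverse-variance weight; consistent when more than half the weight
  comes from valid instruments. SE by seeded parametric bootstrap.
- **MR-Egger**: weighted regression with a free intercept; a nonzero
  intercept indicates directional pleiotropy, and $I^2_{GX}$ quantifies
  attenuation of the slope by exposure measurement error.
- **MR-PRESSO**: a simulation-based residual-sum test that flags
  pleiotropic outliers (Bonferroni-adjusted per-variant tails) and
  re-estimates without them.
- **MR-RAPS** (simple overdispersed form): profile likelihood in
  $(\theta, \tau^2)$ with per-variant variance
  $\sigma_{Yj}^2 + \theta^2\sigma_{Xj}^2 + \tau^2$, propagating
  exposure-side measurement error against weak-instrument bias.

Martingale-scale estimates are converted to years of life lost by
multiplying by 2.2869 (fathers) or 2.5863 (mothers) — offspring share
half their genetic endowment with each parent — and then by 10
(actuarial rule of thumb). Sex differences use
$z = (\hat\theta_W - \hat\theta_M)/\sqrt{SE_M^2 + SE_W^2}$, and the
sex-specific years-of-life-lost estimates are pooled by fixed-effect
inverse-variance meta-analysis.

## Worked example

```python
from mrlifespan import (SimulationConfig, simulate_panel, harmonize_tables,
                        ivw_multiplicative_random, martingale_to_years,
                        instrument_strength_summary)

cfg = SimulationConfig(seed=7, theta_true=0.020, maf_range=(0.05, 0.45))
exposure, outcome, truth = simulate_panel(cfg)
instruments, report = harmonize_tables(exposure, outcome)
est = ivw_multiplicative_random(instruments)
years = martingale_to_years(est, "father")
strength = instrument_strength_summary(instruments)
```

Output:

```
instruments retained: 178 (sign-flipped during harmonization: 28)
mean F = 60, variance explained = 6.4%
IVW (multiplicative random effects): beta = 0.019 (SE 0.006, p = 0.002)
Cochran's Q = 156.1 (p = 0.87)
years of life lost per unit effect size: 0.44 (95% CI 0.16 to 0.71)
```

The generator planted a true causal slope of 0.020 on the martingale
scale across 178 instruments explaining ~6.5% of exposure variance; the
IVW estimate recovers it (0.019), and the conversion reads as 0.44 years
of life lost per unit increase in effect size of genetically predicted
BMR. The harmonization report confirms that the 28 outcome rows whose
allele labels were stored in the opposite orientation were sign-corrected.

A command-line interface mirrors the workflow
(`mrlifespan simulate | validate | select | harmonize | estimate |
report | power | run`); `mrlifespan run --config study.yaml` executes the
full two-stratum study plan (all instruments and excluding
confounder-flagged ones, every estimator, sex comparison, overall
meta-analysis) and writes deterministic TSV results.

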