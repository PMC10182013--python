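"""Conversion of pooled MR estimates to interpretable lifespan scales.

The primary outcome GWAS expresses parental attained age as
rank-normalized martingale residuals of a Cox model, with a positive
value encoding a *reduced* attained age.  An effect on that scale is
converted to years of life lost by an established approximation: multiply
by 2.2869 for fathers or 2.5863 for mothers (offspring share half their
genetic endowment with each parent), then by 10 (actuarial rule of
thumb).  A positive ``years_lost`` therefore means years of life lost per
unit increase in effect size of the genetically predicted exposure.

Survival-to-old-age outcomes are on the log-odds scale and are reported
as odds ratios.  Sex differences are assessed with a z-test
(women - men), and sex-specific estimates are pooled with a fixed-effect
inverse-variance meta-analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .mr_estimators import MREstimate, Z_95

__all__ = [
    "LifespanEffect",
    "OddsRatioEffect",
    "SexComparison",
    "PooledEffect",
    "ReportingError",
    "FATHER_FACTOR",
    "MOTHER_FACTOR",
    "ACTUARIAL_FACTOR",
    "martingale_to_years",
    "logodds_to_or",
    "sex_difference_test",
    "meta_fixed_effect",
]

FATHER_FACTOR = 2.2869
MOTHER_FACTOR = 2.5863
ACTUARIAL_FACTOR = 10.0

_PARENT_FACTORS = {"father": FATHER_FACTOR, "mother": MOTHER_FACTOR}


class ReportingError(ValueError):
    pass


@dataclass(frozen=True)
class LifespanEffect:
    """MR estimate translated to years of life lost for one parent."""

    parent: str
    years_lost: float
    se_years: float
    ci_low_years: float
    ci_high_years: float
    pvalue: float
    method: str
    source: MREstimate | None = None


@dataclass(frozen=True)
class OddsRatioEffect:
    """Log-odds MR estimate exponentiated to an odds ratio of survival."""

    or_: float
    ci_low: float
    ci_high: float
    pvalue: float
    method: str
    source: MREstimate | None = None


@dataclass(frozen=True)
class SexComparison:
    """z-test for a sex difference, signed as women minus men."""

    estimate_men: float
    se_men: float
    estimate_women: float
    se_women: float
    z: float
    pvalue: float


@dataclass(frozen=True)
class PooledEffect:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float


def conversion_factor(
    parent: str,
    *,
    parent_factors: dict[str, float] | None = None,
    actuarial_factor: float = ACTUARIAL_FACTOR,
) -> float:
    factors = parent_factors or _PARENT_FACTORS
    if parent not in factors:
        raise ReportingError(
            f"unknown parent label {parent!r}; expected one of {sorted(factors)}"
        )
    return factors[parent] * actuarial_factor


def martingale_to_years(
    estimate: MREstimate,
    parent: str,
    *,
    parent_factors: dict[str, float] | None = None,
    actuarial_factor: float = ACTUARIAL_FACTOR,
) -> LifespanEffect:
    """Convert a martingale-scale estimate to years of life lost.

    The estimate, SE and CI are all scaled by the parent-specific factor
    times the actuarial factor; the conversion is exactly linear, so the
    p-value is unchanged.
    """
    c = conversion_factor(
        parent, parent_factors=parent_factors, actuarial_factor=actuarial_factor
    )
    return LifespanEffect(
        parent=parent,
        years_lost=estimate.estimate * c,
        se_years=estimate.se * c,
        ci_low_years=estimate.estimate * c - Z_95 * estimate.se * c,
        ci_high_years=estimate.estimate * c + Z_95 * estimate.se * c,
        pvalue=estimate.pvalue,
        method=estimate.method,
        source=estimate,
    )


def logodds_to_or(estimate: MREstimate) -> OddsRatioEffect:
    """Exponentiate a log-odds estimate and its CI bounds to odds ratios."""
    return OddsRatioEffect(
        or_=math.exp(estimate.estimate),
        ci_low=math.exp(estimate.estimate - Z_95 * estimate.se),
        ci_high=math.exp(estimate.estimate + Z_95 * estimate.se),
        pvalue=estimate.pvalue,
        method=estimate.method,
        source=estimate,
    )


def _effect_and_se(obj) -> tuple[float, float]:
    if isinstance(obj, LifespanEffect):
        return obj.years_lost, obj.se_years
    if isinstance(obj, MREstimate):
        return obj.estimate, obj.se
    if isinstance(obj, PooledEffect):
        return obj.estimate, obj.se
    raise ReportingError(f"cannot extract effect and SE from {type(obj).__name__}")


def sex_difference_test(men, women) -> SexComparison:
    """z-test comparing a women-stratum estimate with a men-stratum one.

    ``z = (women - men) / sqrt(se_men^2 + se_women^2)``; positive z means
    a larger effect in women.  Both inputs must come from the same
    estimator.
    """
    method_m = getattr(men, "method", None)
    method_w = getattr(women, "method", None)
    if method_m is not None and method_w is not None and method_m != method_w:
        raise ReportingError(
            f"sex comparison across methods: {method_m!r} vs {method_w!r}"
        )
    em, sm = _effect_and_se(men)
    ew, sw = _effect_and_se(women)
    z = (ew - em) / math.sqrt(sm**2 + sw**2)
    return SexComparison(
        estimate_men=em,
        se_men=sm,
        estimate_women=ew,
        se_women=sw,
        z=z,
        pvalue=float(2 * stats.norm.sf(abs(z))),
    )


def meta_fixed_effect(estimates: Sequence) -> PooledEffect:
    """Fixed-effect inverse-variance pool of estimates on a common scale."""
    if len(estimates) < 2:
        raise ReportingError("meta-analysis requires >= 2 estimates")
    kinds = set()
    pairs = []
    for e in estimates:
        if isinstance(e, LifespanEffect):
            kinds.add("years")
        elif isinstance(e, (MREstimate, PooledEffect)):
            kinds.add("beta")
        pairs.append(_effect_and_se(e))
    if len(kinds) > 1:
        raise ReportingError("cannot pool estimates on mixed scales")
    wsum = sum(1 / s**2 for _, s in pairs)
    est = sum(e / s**2 for e, s in pairs) / wsum
    se = math.sqrt(1 / wsum)
    return PooledEffect(
        estimate=est,
        se=se,
        ci_low=est - Z_95 * se,
        ci_high=est + Z_95 * se,
        pvalue=float(2 * stats.norm.sf(abs(est) / se)),
    )
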