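"""Post hoc power and detectable-effect size for MR with a continuous outcome.

The effective sample size of a two-sample MR analysis is approximately
the outcome sample size times the proportion of exposure variance
explained by the instruments (r^2).  For a causal effect ``b`` on an
outcome with standard deviation ``sigma``, the test statistic is
approximately normal with non-centrality ``|b| * sqrt(n * r2) / sigma``,
giving two-sided power

    Phi(ncp - z_{1-alpha/2}) + Phi(-ncp - z_{1-alpha/2}).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerInput", "PowerError", "mr_power", "detectable_effect"]


class PowerError(ValueError):
    pass


@dataclass(frozen=True)
class PowerInput:
    """Inputs for an MR power calculation.

    ``n``: outcome-GWAS sample size; ``r2``: total exposure variance
    explained by the instruments; ``effect``: causal effect on the
    outcome's analysis scale; ``outcome_sd`` defaults to 1 (rank-
    normalized residual scale).
    """

    n: float
    r2: float
    effect: float
    alpha: float = 0.05
    outcome_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise PowerError("n must be >= 1")
        if not (0 < self.r2 < 1):
            raise PowerError("r2 must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise PowerError("alpha must be in (0, 1)")
        if self.outcome_sd <= 0:
            raise PowerError("outcome_sd must be positive")


def mr_power(inp: PowerInput) -> float:
    """Two-sided power; equals alpha at zero effect, increasing in
    |effect|, n and r2."""
    z_crit = stats.norm.ppf(1 - inp.alpha / 2)
    ncp = abs(inp.effect) * (inp.n * inp.r2) ** 0.5 / inp.outcome_sd
    return float(stats.norm.cdf(ncp - z_crit) + stats.norm.cdf(-ncp - z_crit))


def detectable_effect(
    n: float,
    r2: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
    *,
    outcome_sd: float = 1.0,
    tol: float = 1e-8,
) -> float:
    """Smallest |effect| reaching the target power, by bisection.

    Power is strictly increasing in |effect|, so the monotone branch is
    inverted to ``tol`` absolute precision.
    """
    if not (alpha < target_power < 1):
        raise PowerError("target_power must lie in (alpha, 1)")
    lo, hi = 0.0, 1.0
    while (
        mr_power(PowerInput(n=n, r2=r2, effect=hi, alpha=alpha, outcome_sd=outcome_sd))
        < target_power
    ):
        hi *= 2
        if hi > 1e12:
            raise PowerError("could not bracket the detectable effect")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        p = mr_power(
            PowerInput(n=n, r2=r2, effect=mid, alpha=alpha, outcome_sd=outcome_sd)
        )
        if p >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
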