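"""Two-sample MR estimators with heterogeneity and pleiotropy diagnostics.

Given J harmonized instruments with exposure effects ``bx_j`` (SE
``sx_j``) and outcome effects ``by_j`` (SE ``sy_j``), each instrument's
Wald ratio ``theta_j = by_j / bx_j`` estimates the causal effect of the
exposure on the outcome, with first-order (Fieller first-term) standard
error ``sy_j / |bx_j|``.  The pooled estimators implemented here are:

- inverse-variance weighting with multiplicative random effects (IVW-MRE):
  a zero-intercept weighted regression of ``by`` on ``bx`` with weights
  ``1/sy^2``, its SE inflated by an overdispersion factor
  ``phi = max(1, Q/(J-1))`` derived from Cochran's Q and floored at one so
  the random-effects SE never undercuts the fixed-effect SE;
- the weighted median, consistent when more than half the weight comes
  from valid instruments, with a seeded parametric-bootstrap SE;
- MR-Egger regression, whose intercept tests for directional pleiotropy
  and whose I^2_GX statistic measures attenuation from exposure
  measurement error;
- MR-PRESSO, a simulation-based residual-sum-and-outlier procedure that
  detects pleiotropic outliers and re-estimates without them;
- MR-RAPS in its simple overdispersed form: a profile likelihood in
  (theta, tau^2) that propagates exposure-side measurement error, guarding
  against weak-instrument bias.

All estimator p-values are two-sided normal, ``2 * Phi(-|est/se|)``, and
95% confidence intervals are ``est +/- 1.96 * se``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .harmonization import HarmonizedInstrument

__all__ = [
    "WaldRatio",
    "MREstimate",
    "EggerResult",
    "PressoResult",
    "StrengthSummary",
    "EstimationError",
    "wald_ratio",
    "ivw_multiplicative_random",
    "cochran_q",
    "weighted_median",
    "egger",
    "mr_presso",
    "mr_raps",
    "instrument_strength_summary",
]

Z_95 = 1.96


class EstimationError(ValueError):
    """Raised for degenerate inputs or failed optimization."""


@dataclass(frozen=True)
class WaldRatio:
    """Per-variant causal estimate with instrument-strength diagnostics."""

    variant_id: str
    theta: float
    se_theta: float
    f_stat: float
    r2_variant: float | None


@dataclass(frozen=True)
class MREstimate:
    """Pooled causal effect from one estimator."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_instruments: int
    cochran_q: float | None = None
    q_pvalue: float | None = None
    egger_intercept_p: float | None = None
    i2_gx: float | None = None
    outliers: tuple[str, ...] | None = None
    overdispersion_tau2: float | None = None


@dataclass(frozen=True)
class EggerResult:
    slope: MREstimate
    intercept: MREstimate
    i2_gx: float


@dataclass(frozen=True)
class PressoResult:
    global_p: float
    outlier_pvalues: dict[str, float]
    outliers: tuple[str, ...]
    raw: MREstimate
    corrected: MREstimate
    distortion_p: float | None


@dataclass(frozen=True)
class StrengthSummary:
    mean_f: float
    min_f: float
    max_f: float
    total_r2: float | None
    i2_gx: float | None


def _two_sided_p(estimate: float, se: float) -> float:
    return float(2 * stats.norm.sf(abs(estimate) / se))


def _estimate(method, est, se, j, **kw) -> MREstimate:
    return MREstimate(
        method=method,
        estimate=float(est),
        se=float(se),
        ci_low=float(est - Z_95 * se),
        ci_high=float(est + Z_95 * se),
        pvalue=_two_sided_p(est, se),
        n_instruments=j,
        **kw,
    )


def _arrays(
    instruments: Sequence[HarmonizedInstrument], minimum: int, method: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    kept = [h for h in instruments if h.retained]
    if len(kept) < minimum:
        raise EstimationError(
            f"{method} requires >= {minimum} instruments, got {len(kept)}"
        )
    bx = np.array([h.bx for h in kept], dtype=float)
    sx = np.array([h.se_x for h in kept], dtype=float)
    by = np.array([h.by for h in kept], dtype=float)
    sy = np.array([h.se_y for h in kept], dtype=float)
    if np.any(bx == 0):
        raise EstimationError(
            "instrument with bx = 0; exclude upstream via the significance filter"
        )
    ids = [h.variant_id for h in kept]
    return bx, sx, by, sy, ids


def wald_ratio(
    bx: float,
    se_x: float,
    by: float,
    se_y: float,
    eaf: float | None = None,
    *,
    variant_id: str = "",
) -> WaldRatio:
    """Single-variant Wald ratio with Fieller first-term SE.

    ``theta = by/bx``, ``se = se_y/|bx|``; instrument strength
    ``F = (bx/se_x)^2``; variance in the exposure explained
    ``r2 = bx^2 * 2 * maf * (1 - maf)`` (missing when EAF is missing).
    """
    if bx == 0:
        raise EstimationError("bx must be nonzero for a Wald ratio")
    if se_x <= 0 or se_y <= 0:
        raise EstimationError("standard errors must be positive")
    r2 = None
    if eaf is not None:
        maf = min(eaf, 1 - eaf)
        r2 = bx * bx * 2 * maf * (1 - maf)
    return WaldRatio(
        variant_id=variant_id,
        theta=by / bx,
        se_theta=se_y / abs(bx),
        f_stat=(bx / se_x) ** 2,
        r2_variant=r2,
    )


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    w_reg = 1.0 / sy**2
    denom = float(np.sum(w_reg * bx**2))
    est = float(np.sum(w_reg * bx * by)) / denom
    theta_j = by / bx
    w_j = bx**2 / sy**2
    q = float(np.sum(w_j * (theta_j - est) ** 2))
    return est, denom, q


def ivw_multiplicative_random(
    instruments: Sequence[HarmonizedInstrument],
) -> MREstimate:
    """IVW meta-analysis of Wald ratios with multiplicative random effects.

    Algebraically the zero-intercept weighted regression of ``by`` on
    ``bx`` with weights ``1/sy^2``.  Cochran's Q is computed from the Wald
    ratios with weights ``bx^2/sy^2``; the SE is the fixed-effect SE
    scaled by ``sqrt(max(1, Q/(J-1)))``.
    """
    bx, _, by, sy, _ = _arrays(instruments, 2, "IVW")
    j = len(bx)
    est, denom, q = _ivw_core(bx, by, sy)
    phi = max(1.0, q / (j - 1))
    se = math.sqrt(phi / denom)
    q_p = float(stats.chi2.sf(q, df=j - 1))
    return _estimate("ivw_mre", est, se, j, cochran_q=q, q_pvalue=q_p)


def cochran_q(
    thetas: Sequence[float], weights: Sequence[float]
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic for weighted estimates.

    ``Q = sum w_j (theta_j - theta_bar)^2`` with ``theta_bar`` the
    fixed-weight inverse-variance pool; df = J - 1; upper-tail chi-squared
    p-value.
    """
    t = np.asarray(thetas, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != w.shape:
        raise EstimationError("thetas and weights must have equal length")
    if t.size < 2:
        raise EstimationError("Cochran's Q requires >= 2 entries")
    if np.any(w <= 0):
        raise EstimationError("weights must be positive")
    pooled = float(np.sum(w * t) / np.sum(w))
    q = float(np.sum(w * (t - pooled) ** 2))
    df = t.size - 1
    return q, df, float(stats.chi2.sf(q, df=df))


def _weighted_median_point(theta: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated median: cumulative midpoint ranks, linear
    interpolation at cumulative weight 0.5."""
    order = np.argsort(theta, kind="stable")
    t = theta[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2
    if 0.5 <= s[0]:
        return float(t[0])
    if 0.5 >= s[-1]:
        return float(t[-1])
    return float(np.interp(0.5, s, t))


def weighted_median(
    instruments: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap SE.

    Wald ratios are ordered and the estimate interpolated at 50% of the
    inverse-variance weight ``bx^2/sy^2``; valid when more than half of
    the total weight comes from valid instruments.  The SE is the standard
    deviation of the estimate over ``n_boot`` parametric resamples
    ``theta_j* ~ Normal(theta_j, se_theta_j)`` at the given seed (weights
    held fixed).
    """
    bx, _, by, sy, _ = _arrays(instruments, 3, "weighted median")
    if n_boot < 2:
        raise EstimationError("n_boot must be >= 2")
    j = len(bx)
    theta = by / bx
    se_theta = sy / np.abs(bx)
    w = bx**2 / sy**2
    est = _weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se_theta, size=(n_boot, j))
    boot = np.array([_weighted_median_point(d, w) for d in draws])
    se = float(boot.std(ddof=1))
    return _estimate("weighted_median", est, se, j)


def _i2_gx(bx: np.ndarray, sx: np.ndarray) -> float:
    """I^2_GX: relative measurement-error-free variation among exposure
    effects, from the Q statistic of bx weighted by 1/sx^2."""
    w = 1.0 / sx**2
    mean_bx = float(np.sum(w * bx) / np.sum(w))
    q_gx = float(np.sum(w * (bx - mean_bx) ** 2))
    if q_gx <= 0:
        return 0.0
    j = len(bx)
    return max(0.0, (q_gx - (j - 1)) / q_gx)


def egger(instruments: Sequence[HarmonizedInstrument]) -> EggerResult:
    """MR-Egger regression: ``by = alpha + theta * bx``, weights 1/sy^2.

    Instruments are first oriented so every ``bx >= 0`` (flipping bx and
    by jointly), which makes the orientation-dependent intercept test
    deterministic.  SEs use multiplicative overdispersion
    ``phi = max(1, RSS_w / (J - 2))``.  A nonzero intercept indicates
    directional pleiotropy; I^2_GX near 1 indicates the slope is not
    attenuated by exposure measurement error.
    """
    bx, sx, by, sy, _ = _arrays(instruments, 3, "MR-Egger")
    j = len(bx)
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip

    if np.allclose(bx, bx[0]):
        raise EstimationError(
            "all exposure effects identical after orientation; "
            "Egger slope and intercept are unidentifiable"
        )
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    xtw = x.T * w
    xtwx = xtw @ x
    coef = np.linalg.solve(xtwx, xtw @ by)
    resid = by - x @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / (j - 2))
    cov = phi * np.linalg.inv(xtwx)
    alpha, theta = float(coef[0]), float(coef[1])
    se_alpha, se_theta = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    i2 = _i2_gx(bx, sx)
    intercept = _estimate("egger_intercept", alpha, se_alpha, j)
    slope = _estimate(
        "egger",
        theta,
        se_theta,
        j,
        egger_intercept_p=intercept.pvalue,
        i2_gx=i2,
    )
    return EggerResult(slope=slope, intercept=intercept, i2_gx=i2)


def _loo_ivw(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, one per instrument."""
    w = 1.0 / sy**2
    num = np.sum(w * bx * by)
    den = np.sum(w * bx**2)
    return (num - w * bx * by) / (den - w * bx**2)


def mr_presso(
    instruments: Sequence[HarmonizedInstrument],
    n_sim: int = 10_000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """MR-PRESSO: pleiotropy residual sum and outlier test.

    The observed statistic is the weighted residual sum
    ``RSS = sum_j (by_j - theta_loo_j * bx_j)^2 / sy_j^2`` with
    ``theta_loo_j`` the leave-one-out IVW estimate.  A parametric null is
    simulated ``n_sim`` times by redrawing
    ``by*_j ~ N(theta_loo_j * bx_j, sy_j)`` and ``bx*_j ~ N(bx_j, sx_j)``;
    the global p-value is the tail proportion of simulated RSS at or above
    the observed one.  Per-variant outlier p-values come from each
    variant's simulated residual tail, Bonferroni-adjusted by J; flagged
    outliers are removed and the IVW-MRE estimate recomputed.  The
    distortion p-value compares the observed estimate shift against the
    shift distribution from removing random subsets of the same size.
    """
    bx, sx, by, sy, ids = _arrays(instruments, 4, "MR-PRESSO")
    if n_sim < 1:
        raise EstimationError("n_sim must be >= 1")
    j = len(bx)
    rng = np.random.default_rng(seed)

    loo = _loo_ivw(bx, by, sy)
    resid_obs = (by - loo * bx) ** 2 / sy**2
    rss_obs = float(resid_obs.sum())

    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(loo * bx, sy, size=(n_sim, j))
    w = 1.0 / sy**2
    num = np.sum(w * bx_star * by_star, axis=1, keepdims=True)
    den = np.sum(w * bx_star**2, axis=1, keepdims=True)
    loo_star = (num - w * bx_star * by_star) / (den - w * bx_star**2)
    resid_star = (by_star - loo_star * bx_star) ** 2 / sy**2

    # add-one Monte-Carlo p-values: never exactly zero at finite n_sim
    rss_star = resid_star.sum(axis=1)
    global_p = float((np.sum(rss_star >= rss_obs) + 1) / (n_sim + 1))

    tail = (np.sum(resid_star >= resid_obs, axis=0) + 1) / (n_sim + 1)
    adj = np.minimum(1.0, tail * j)
    outlier_p = {vid: float(p) for vid, p in zip(ids, adj)}
    outliers = tuple(vid for vid, p in zip(ids, adj) if p < outlier_alpha)

    raw = ivw_multiplicative_random(
        [h for h in instruments if h.retained]
    )
    if outliers:
        keep_mask = ~np.isin(ids, outliers)
        kept = [h for h in instruments if h.retained and h.variant_id not in outliers]
        corrected = ivw_multiplicative_random(kept)
        corrected = MREstimate(
            **{**corrected.__dict__, "method": "presso_corrected",
               "outliers": outliers}
        )
        # distortion: shift from removing random subsets of the same size
        n_out = len(outliers)
        shift_obs = raw.estimate - corrected.estimate
        shifts = np.empty(n_sim)
        for s in range(n_sim):
            drop = rng.choice(j, size=n_out, replace=False)
            mask = np.ones(j, dtype=bool)
            mask[drop] = False
            est_s, _, _ = _ivw_core(bx[mask], by[mask], sy[mask])
            shifts[s] = raw.estimate - est_s
        distortion_p = float(
            (np.sum(np.abs(shifts) >= abs(shift_obs)) + 1) / (n_sim + 1)
        )
    else:
        corrected = MREstimate(
            **{**raw.__dict__, "method": "presso_corrected", "outliers": ()}
        )
        distortion_p = None

    raw = MREstimate(**{**raw.__dict__, "method": "presso_raw"})
    return PressoResult(
        global_p=global_p,
        outlier_pvalues=outlier_p,
        outliers=outliers,
        raw=raw,
        corrected=corrected,
        distortion_p=distortion_p,
    )


def _raps_neg_profile_ll(theta, tau2, bx, sx, by, sy):
    v = sy**2 + theta**2 * sx**2 + tau2
    return 0.5 * float(np.sum((by - theta * bx) ** 2 / v + np.log(v)))


def mr_raps(
    instruments: Sequence[HarmonizedInstrument],
    tol: float = 1e-10,
    max_iter: int = 200,
    *,
    fit_overdispersion: bool = True,
) -> MREstimate:
    """Robust adjusted profile score estimator (simple overdispersed form).

    Maximizes the profile log-likelihood

        l(theta, tau2) = -1/2 sum_j [ (by_j - theta bx_j)^2 / v_j + log v_j ],
        v_j = sy_j^2 + theta^2 sx_j^2 + tau2,   tau2 >= 0,

    by coordinate descent: a 1-d minimization in theta at fixed tau2,
    then in tau2 at fixed theta, until successive (theta, tau2) change by
    less than ``tol``.  The variance ``v_j`` carries the exposure-side
    measurement error ``sx_j`` (the protection against weak-instrument
    bias) and the overdispersion ``tau2`` models balanced normal
    pleiotropy.  The SE comes from the observed information at the
    optimum.
    """
    bx, sx, by, sy, _ = _arrays(instruments, 3, "MR-RAPS")
    j = len(bx)

    # fixed-effect IVW start
    theta = float(np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2))
    tau2 = 0.0
    converged = False
    for _ in range(max_iter):
        theta_old, tau2_old = theta, tau2
        res = optimize.minimize_scalar(
            lambda t: _raps_neg_profile_ll(t, tau2, bx, sx, by, sy),
            bracket=(theta - 1.0, theta, theta + 1.0)
            if theta != 0
            else (-1.0, 0.0, 1.0),
            method="brent",
            options={"xtol": tol / 10},
        )
        theta = float(res.x)
        if fit_overdispersion:
            res2 = optimize.minimize_scalar(
                lambda t2: _raps_neg_profile_ll(theta, t2, bx, sx, by, sy),
                bounds=(0.0, max(1.0, 100 * float(np.mean(sy**2)), 10 * tau2)),
                method="bounded",
                options={"xatol": tol / 10},
            )
            tau2 = float(res2.x)
        if abs(theta - theta_old) < tol and abs(tau2 - tau2_old) < tol:
            converged = True
            break
    if not converged:
        grad = optimize.approx_fprime(
            np.array([theta, tau2]),
            lambda p: _raps_neg_profile_ll(p[0], max(p[1], 0.0), bx, sx, by, sy),
            1e-8,
        )
        raise EstimationError(
            f"MR-RAPS failed to converge in {max_iter} iterations; "
            f"last iterate theta={theta:.6g}, tau2={tau2:.6g}, "
            f"gradient norm={float(np.linalg.norm(grad)):.3g}"
        )

    # observed information for theta (numerical second derivative of the
    # negative profile log-likelihood, tau2 profiled out at the optimum)
    h = max(1e-6, 1e-6 * abs(theta))
    f0 = _raps_neg_profile_ll(theta, tau2, bx, sx, by, sy)
    fp = _raps_neg_profile_ll(theta + h, tau2, bx, sx, by, sy)
    fm = _raps_neg_profile_ll(theta - h, tau2, bx, sx, by, sy)
    info = (fp - 2 * f0 + fm) / h**2
    if info <= 0:
        raise EstimationError("non-positive observed information in MR-RAPS")
    se = math.sqrt(1.0 / info)
    return _estimate("raps", theta, se, j, overdispersion_tau2=tau2)


def instrument_strength_summary(
    instruments: Sequence[HarmonizedInstrument],
) -> StrengthSummary:
    """Mean/min/max per-variant F, summed variance explained, I^2_GX.

    F uses the exposure association only; the total r^2 sums the
    per-variant ``bx^2 * 2 * maf * (1 - maf)`` contributions (missing when
    no instrument carries an EAF).
    """
    kept = [h for h in instruments if h.retained]
    if not kept:
        raise EstimationError("no retained instruments")
    bx = np.array([h.bx for h in kept])
    sx = np.array([h.se_x for h in kept])
    f = (bx / sx) ** 2
    r2_parts = [
        wald_ratio(h.bx, h.se_x, h.by, h.se_y, h.eaf_exposure).r2_variant
        for h in kept
        if h.eaf_exposure is not None
    ]
    total_r2 = float(np.sum(r2_parts)) if r2_parts else None
    i2 = _i2_gx(np.abs(bx), sx) if len(kept) >= 2 else None
    return StrengthSummary(
        mean_f=float(f.mean()),
        min_f=float(f.min()),
        max_f=float(f.max()),
        total_r2=total_r2,
        i2_gx=i2,
    )
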