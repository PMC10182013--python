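import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrlifespan.harmonization import HarmonizedInstrument, Action
from mrlifespan.mr_estimators import (
    EstimationError,
    cochran_q,
    egger,
    instrument_strength_summary,
    ivw_multiplicative_random,
    mr_presso,
    mr_raps,
    wald_ratio,
    weighted_median,
)
from mrlifespan.synthetic_data import SimulationConfig, simulate_harmonized

from conftest import make_instruments


class TestWaldRatio:
    def test_ratio_and_fieller_se(self):
        w = wald_ratio(0.10, 0.005, 0.05, 0.02)
        assert w.theta == pytest.approx(0.5)
        assert w.se_theta == pytest.approx(0.2)

    def test_f_statistic(self):
        assert wald_ratio(0.03, 0.005, 0.0, 0.01).f_stat == pytest.approx(36.0)

    def test_variance_explained_at_half_frequency(self):
        assert wald_ratio(1.0, 0.1, 0.0, 0.1, eaf=0.5).r2_variant == pytest.approx(0.5)

    def test_missing_eaf_gives_missing_r2(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.01).r2_variant is None

    def test_zero_bx_rejected(self):
        with pytest.raises(EstimationError):
            wald_ratio(0.0, 0.01, 0.0, 0.01)


class TestIVW:
    def test_homogeneous_ratios_recovered_exactly(self):
        inst = make_instruments(
            bx=[0.1, 0.2, 0.1], by=[0.05, 0.10, 0.05], se_y=[0.02] * 3
        )
        e = ivw_multiplicative_random(inst)
        assert e.estimate == pytest.approx(0.5, abs=1e-14)
        assert e.cochran_q == pytest.approx(0.0, abs=1e-20)
        # phi floored at 1: SE equals the fixed-effect SE
        denom = sum(b**2 / 0.02**2 for b in (0.1, 0.2, 0.1))
        assert e.se == pytest.approx((1 / denom) ** 0.5)

    def test_matches_weighted_least_squares_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            j = rng.integers(3, 30)
            bx = rng.normal(0.05, 0.02, j)
            bx[np.abs(bx) < 1e-3] = 1e-3
            by = rng.normal(0.0, 0.01, j)
            sy = rng.uniform(0.005, 0.02, j)
            inst = make_instruments(bx, by, sy)
            e = ivw_multiplicative_random(inst)
            fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
            assert e.estimate == pytest.approx(fit.params[0], rel=1e-10)

    def test_simulation_recovery(self):
        reps = 200
        ests = np.empty(reps)
        for r in range(reps):
            inst, _ = simulate_harmonized(
                SimulationConfig(seed=1000 + r, n_variants=150, theta_true=0.05)
            )
            ests[r] = ivw_multiplicative_random(inst).estimate
        mc_se = ests.std(ddof=1) / reps**0.5
        assert abs(ests.mean() - 0.05) < 3 * mc_se

    def test_requires_two_instruments(self):
        with pytest.raises(EstimationError):
            ivw_multiplicative_random(make_instruments([0.1], [0.05], [0.01]))

    def test_p_value_is_two_sided_normal(self):
        inst = make_instruments(
            bx=[0.1, 0.2, 0.15], by=[0.06, 0.09, 0.05], se_y=[0.02] * 3
        )
        e = ivw_multiplicative_random(inst)
        assert e.pvalue == pytest.approx(2 * stats.norm.sf(abs(e.estimate / e.se)))
        assert e.ci_low == pytest.approx(e.estimate - 1.96 * e.se)


class TestCochranQ:
    def test_identical_ratios(self):
        q, df, p = cochran_q([0.3, 0.3, 0.3], [1.0, 2.0, 3.0])
        assert q == pytest.approx(0.0, abs=1e-15) and p == pytest.approx(1.0)

    def test_two_entry_hand_arithmetic(self):
        q, df, p = cochran_q([0.0, 1.0], [1.0, 1.0])
        assert q == pytest.approx(0.5) and df == 1

    def test_null_distribution_mean(self):
        # homogeneous simulation: Q ~ chi2(J-1)
        rng = np.random.default_rng(5)
        j, reps = 30, 400
        qs = np.empty(reps)
        for r in range(reps):
            theta = rng.normal(0.0, 1.0, j)  # equal unit variances
            qs[r] = cochran_q(theta, np.ones(j))[0]
        mc_se = qs.std(ddof=1) / reps**0.5
        assert abs(qs.mean() - (j - 1)) < 3 * mc_se

    def test_length_mismatch(self):
        with pytest.raises(EstimationError):
            cochran_q([0.1, 0.2], [1.0])


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        inst = make_instruments(
            bx=[0.1, 0.1, 0.1], by=[0.1, 0.2, 0.3], se_y=[0.01] * 3
        )
        e = weighted_median(inst, n_boot=50, seed=1)
        assert e.estimate == pytest.approx(2.0)

    def test_minority_outvoted(self):
        # ratios (0,0,0,10); weights proportional to (0.3,0.3,0.3,0.1)
        bx = np.array([0.3, 0.3, 0.3, 0.1]) ** 0.5
        by = np.array([0.0, 0.0, 0.0, 10.0]) * bx
        inst = make_instruments(bx, by, se_y=[1.0] * 4)
        e = weighted_median(inst, n_boot=50, seed=1)
        assert e.estimate == pytest.approx(0.0, abs=1e-12)

    def test_all_weight_on_one_variant_equals_its_wald_ratio(self):
        bx = np.array([10.0, 0.001, 0.001])
        by = np.array([5.0, 0.0001, 0.00005])
        inst = make_instruments(bx, by, se_y=[0.01] * 3)
        e = weighted_median(inst, n_boot=50, seed=1)
        assert e.estimate == pytest.approx(0.5, abs=1e-6)

    def test_bootstrap_se_reproducible_at_fixed_seed(self):
        inst = make_instruments(
            bx=[0.1, 0.2, 0.15, 0.12], by=[0.06, 0.09, 0.05, 0.07],
            se_y=[0.02] * 4,
        )
        a = weighted_median(inst, n_boot=200, seed=42)
        b = weighted_median(inst, n_boot=200, seed=42)
        assert a.se == b.se

    def test_requires_three_instruments(self):
        with pytest.raises(EstimationError):
            weighted_median(make_instruments([0.1, 0.2], [0.0, 0.0], [0.01, 0.01]))


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.05, 0.10, 0.15, 0.20])
        by = 0.02 + 0.5 * bx
        inst = make_instruments(bx, by, se_y=[0.01] * 4)
        res = egger(inst)
        assert res.intercept.estimate == pytest.approx(0.02, abs=1e-12)
        assert res.slope.estimate == pytest.approx(0.5, abs=1e-10)

    def test_collinear_design_rejected(self):
        inst = make_instruments([0.1] * 4, [0.05] * 4, [0.01] * 4)
        with pytest.raises(EstimationError):
            egger(inst)

    def test_i2_gx_range(self):
        inst, _ = simulate_harmonized(SimulationConfig(seed=3, n_variants=100))
        res = egger(inst)
        assert 0.0 <= res.i2_gx <= 1.0

    def test_balanced_pleiotropy_intercept_size(self):
        # mean-zero pleiotropy: intercept rejection at nominal 5% level
        reps, rejections = 400, 0
        for r in range(reps):
            inst, _ = simulate_harmonized(
                SimulationConfig(
                    seed=20_000 + r, n_variants=100, theta_true=0.05,
                    pleiotropy_model="balanced", pleiotropy_sd=0.002,
                )
            )
            if egger(inst).intercept.pvalue < 0.05:
                rejections += 1
        rate = rejections / reps
        band = 3 * (0.05 * 0.95 / reps) ** 0.5
        assert abs(rate - 0.05) < band + 0.02


class TestPresso:
    def test_planted_outliers_flagged(self):
        cfg = SimulationConfig(
            seed=11, n_variants=50, pleiotropy_model="outliers",
            n_outliers=3, outlier_magnitude=10.0,
        )
        inst, truth = simulate_harmonized(cfg)
        res = mr_presso(inst, n_sim=2000, seed=12)
        planted = {
            vid for vid, flag in zip(truth.variant_ids, truth.outlier_flags) if flag
        }
        assert planted == set(res.outliers)
        assert res.global_p < 0.05
        assert res.distortion_p is not None

    def test_clean_data_no_outliers_corrected_equals_raw(self):
        inst, _ = simulate_harmonized(SimulationConfig(seed=21, n_variants=50))
        res = mr_presso(inst, n_sim=1000, seed=22)
        assert res.outliers == ()
        assert res.corrected.estimate == pytest.approx(res.raw.estimate)
        assert res.distortion_p is None

    def test_zero_sims_is_config_error(self):
        inst, _ = simulate_harmonized(SimulationConfig(seed=1, n_variants=10))
        with pytest.raises(EstimationError):
            mr_presso(inst, n_sim=0, seed=1)

    def test_requires_four_instruments(self):
        with pytest.raises(EstimationError):
            mr_presso(make_instruments([0.1] * 3, [0.0] * 3, [0.01] * 3), seed=1)


class TestRaps:
    def test_no_measurement_error_limit_equals_fixed_effect_ivw(self):
        rng = np.random.default_rng(9)
        bx = rng.normal(0.05, 0.02, 30)
        by = 0.05 * bx + rng.normal(0, 0.005, 30)
        sy = np.full(30, 0.005)
        inst = make_instruments(bx, by, sy, se_x=np.full(30, 1e-12))
        e = mr_raps(inst, fit_overdispersion=False)
        fixed = np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2)
        assert e.estimate == pytest.approx(fixed, abs=1e-8)
        assert e.overdispersion_tau2 == pytest.approx(0.0, abs=1e-12)

    def test_overdispersion_recovery(self):
        # tau2 = 4 x mean sey^2 planted as balanced pleiotropy
        reps = 60
        thetas, tau2s, true_tau2 = [], [], None
        for r in range(reps):
            cfg = SimulationConfig(
                seed=30_000 + r, n_variants=200, theta_true=0.05,
                pleiotropy_model="balanced", pleiotropy_sd=0.0,
            )
            inst, truth = simulate_harmonized(cfg)
            if true_tau2 is None:
                true_tau2 = 4 * float(np.mean(truth.se_y**2))
            rng = np.random.default_rng(40_000 + r)
            inst = [
                HarmonizedInstrument(
                    **{**h.__dict__, "by": h.by + rng.normal(0, true_tau2**0.5)}
                )
                for h in inst
            ]
            e = mr_raps(inst)
            thetas.append(e.estimate)
            tau2s.append(e.overdispersion_tau2)
        thetas = np.array(thetas)
        mc_se = thetas.std(ddof=1) / reps**0.5
        assert abs(thetas.mean() - 0.05) < 3 * mc_se
        assert abs(np.mean(tau2s) - true_tau2) < 0.25 * true_tau2


class TestInvariants:
    def test_scale_equivariance(self):
        inst, _ = simulate_harmonized(SimulationConfig(seed=2, n_variants=40))
        c = 3.7
        scaled = [
            HarmonizedInstrument(
                **{**h.__dict__, "by": h.by * c, "se_y": h.se_y * c}
            )
            for h in inst
        ]
        for f in (
            ivw_multiplicative_random,
            lambda x: weighted_median(x, n_boot=100, seed=5),
            lambda x: egger(x).slope,
            mr_raps,
        ):
            a, b = f(inst), f(scaled)
            assert b.estimate == pytest.approx(c * a.estimate, rel=1e-6)
            assert b.se == pytest.approx(c * a.se, rel=1e-4)

    def test_orientation_invariance(self):
        inst, _ = simulate_harmonized(SimulationConfig(seed=4, n_variants=40))
        rng = np.random.default_rng(6)
        signs = rng.choice([-1.0, 1.0], size=len(inst))
        flipped = [
            HarmonizedInstrument(
                **{**h.__dict__, "bx": h.bx * s, "by": h.by * s}
            )
            for h, s in zip(inst, signs)
        ]
        for f in (
            ivw_multiplicative_random,
            lambda x: weighted_median(x, n_boot=100, seed=5),
            lambda x: egger(x).slope,
            mr_raps,
        ):
            assert f(flipped).estimate == pytest.approx(
                f(inst).estimate, rel=1e-8
            )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mre_se_never_undercuts_fixed_effect_se(self, seed):
        inst, _ = simulate_harmonized(
            SimulationConfig(seed=seed, n_variants=20,
                             pleiotropy_model="balanced", pleiotropy_sd=0.003)
        )
        e = ivw_multiplicative_random(inst)
        bx = np.array([h.bx for h in inst])
        sy = np.array([h.se_y for h in inst])
        fixed_se = (1 / np.sum(bx**2 / sy**2)) ** 0.5
        assert e.se >= fixed_se - 1e-15


class TestStrengthSummary:
    def test_single_instrument(self):
        inst = make_instruments([0.03], [0.0], [0.01], se_x=[0.005])
        s = instrument_strength_summary(inst)
        assert s.mean_f == s.min_f == s.max_f == pytest.approx(36.0)

    def test_total_r2_sums_contributions(self):
        bx = np.array([0.1, 0.2])
        eaf = np.array([0.5, 0.5])
        inst = make_instruments(bx, [0.0, 0.0], [0.01, 0.01], eaf=eaf)
        s = instrument_strength_summary(inst)
        assert s.total_r2 == pytest.approx(0.5 * (0.01 + 0.04))

    def test_generated_panel_matches_targets(self):
        cfg = SimulationConfig(seed=77, n_variants=178, total_r2=0.065)
        inst, _ = simulate_harmonized(cfg)
        s = instrument_strength_summary(inst)
        target_mean_f = 0.065 * cfg.n_exposure / 178
        assert abs(s.total_r2 - 0.065) / 0.065 < 0.10
        assert abs(s.mean_f - target_mean_f) / target_mean_f < 0.20
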