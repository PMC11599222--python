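"""Univariable MR estimators, heterogeneity, pleiotropy and outlier tests."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mrmediate as mm
from mrmediate import DataError, IdentificationError
from mrmediate.uvmr import _egger_fit, _weighted_median, bh_fdr, directional_consistency

from conftest import aligned_hset, make_hset


class TestIvw:
    def test_single_snp_degrades_to_wald_ratio(self):
        h = make_hset([0.1], [0.01], [0.05], [0.01])
        with pytest.warns(UserWarning, match="Wald ratio"):
            est = mm.ivw_estimate(h)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_perfectly_proportional_data(self, proportional_hset):
        est_re = mm.ivw_estimate(proportional_hset, random_effects=True)
        est_fe = mm.ivw_estimate(proportional_hset, random_effects=False)
        assert est_re.beta == pytest.approx(0.5, rel=1e-12)
        # Q = 0, so the random-effects inflation factor is exactly 1
        assert est_re.se == pytest.approx(est_fe.se, rel=1e-12)
        q = mm.cochran_q(proportional_hset, "ivw")
        assert q.q == pytest.approx(0.0, abs=1e-20)
        assert q.pvalue == pytest.approx(1.0)

    def test_fixed_se_never_exceeds_random_effects_se(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            j = int(rng.integers(3, 30))
            h = make_hset(
                rng.normal(0.1, 0.05, j), rng.uniform(0.005, 0.02, j),
                rng.normal(0.05, 0.05, j), rng.uniform(0.005, 0.02, j),
            )
            fe = mm.ivw_estimate(h, random_effects=False)
            re = mm.ivw_estimate(h, random_effects=True)
            assert fe.se <= re.se + 1e-15
            assert fe.beta == re.beta

    def test_ci_is_normal_approximation(self):
        h = make_hset([0.1, 0.2, 0.15], 0.01, [0.06, 0.09, 0.08], 0.01)
        e = mm.ivw_estimate(h)
        assert e.ci_low == pytest.approx(e.beta - 1.959963984540054 * e.se)
        assert e.ci_high == pytest.approx(e.beta + 1.959963984540054 * e.se)

    @given(st.lists(st.booleans(), min_size=5, max_size=5))
    def test_invariant_under_joint_sign_flip(self, flips):
        bx = np.array([0.08, 0.12, 0.2, 0.15, 0.1])
        by = np.array([0.05, 0.07, 0.09, 0.1, 0.04])
        s = np.where(np.array(flips), -1.0, 1.0)
        e1 = mm.ivw_estimate(make_hset(bx, 0.01, by, 0.01))
        e2 = mm.ivw_estimate(make_hset(s * bx, 0.01, s * by, 0.01))
        assert e2.beta == pytest.approx(e1.beta, rel=1e-12)
        assert e2.se == pytest.approx(e1.se, rel=1e-12)

    def test_all_zero_exposure_betas_not_identified(self):
        with pytest.raises(IdentificationError):
            mm.ivw_estimate(make_hset([0.0, 0.0], 0.01, [0.1, 0.2], 0.01))


class TestEgger:
    def test_two_point_line_recovered_exactly(self):
        # two oriented points with equal weights define the fit
        intercept, slope, *_ = _egger_fit(
            np.array([0.1, 0.2]), np.array([0.07, 0.12]), np.array([1.0, 1.0])
        )
        assert slope == pytest.approx(0.5, rel=1e-12)
        assert intercept == pytest.approx(0.02, rel=1e-12)

    def test_requires_three_snps(self):
        with pytest.raises(DataError):
            mm.egger_estimate(make_hset([0.1, 0.2], 0.01, [0.05, 0.1], 0.01))

    def test_proportional_data_gives_zero_intercept_and_ivw_slope(self, proportional_hset):
        egger = mm.egger_estimate(proportional_hset)
        ivw = mm.ivw_estimate(proportional_hset)
        assert egger.intercept == pytest.approx(0.0, abs=1e-14)
        assert egger.beta == pytest.approx(ivw.beta, rel=1e-12)

    def test_slope_invariant_to_input_orientation(self):
        bx = np.array([0.1, -0.2, 0.15, -0.08])
        by = np.array([0.06, -0.11, 0.09, -0.05])
        e1 = mm.egger_estimate(make_hset(bx, 0.01, by, 0.01))
        e2 = mm.egger_estimate(make_hset(-bx, 0.01, -by, 0.01))
        assert e1.beta == pytest.approx(e2.beta, rel=1e-12)
        assert e1.intercept == pytest.approx(e2.intercept, rel=1e-12)

    def test_directional_pleiotropy_offset_recovered(self):
        # offsets ride on the exposure-increasing allele, so the oriented
        # regression sees a constant +delta and the intercept estimates it
        delta = 0.01
        intercepts = []
        for r in range(25):
            sc = mm.validation_scenario(
                seed=3000 + r, pleiotropy="directional", pleiotropy_magnitude=delta
            )
            summaries, _ = mm.simulate_summary_stats(sc)
            rsids = summaries["exposure"].table["rsid"][:100]
            h = aligned_hset(summaries, "exposure", "outcome", rsids)
            intercepts.append(mm.egger_estimate(h).intercept)
        mean = np.mean(intercepts)
        mcse = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert abs(mean - delta) < 3 * mcse + 1e-4

    def test_intercept_test_reports_egger_intercept_row(self):
        h = make_hset([0.1, 0.2, 0.15, 0.3], 0.01, [0.08, 0.12, 0.1, 0.17], 0.01)
        est = mm.egger_estimate(h)
        pl = mm.egger_intercept_test(h)
        assert pl.intercept == est.intercept
        assert pl.se == est.intercept_se
        assert pl.pvalue == est.intercept_p

    def test_exact_null_pleiotropy_gives_zero_intercept(self, proportional_hset):
        assert mm.egger_intercept_test(proportional_hset).intercept == pytest.approx(
            0.0, abs=1e-14
        )


class TestWeightedMedian:
    def test_middle_order_statistic_with_equal_weights(self):
        assert _weighted_median(
            np.array([0.2, 0.5, 0.9]), np.ones(3)
        ) == pytest.approx(0.5, rel=1e-12)

    def test_concentrated_weight_pins_the_estimate(self):
        r = np.array([0.1, 0.8, 0.4])
        w = np.array([0.01, 0.98, 0.01])
        assert abs(_weighted_median(r, w) - 0.8) < 0.02

    def test_equals_unweighted_median_when_weights_equal(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            r = rng.normal(0.5, 0.2, 9)
            est = _weighted_median(r, np.ones(9))
            # interpolated weighted median at equal weights is the sample median
            assert est == pytest.approx(np.median(r), rel=1e-10)

    def test_estimator_interface_and_bootstrap_se(self):
        bx = np.array([0.1, 0.2, 0.15, 0.12, 0.3])
        h = make_hset(bx, 0.005, 0.5 * bx, 0.01)
        est = mm.weighted_median(h, n_boot=300, seed=4)
        assert est.method == "weighted_median"
        assert est.beta == pytest.approx(0.5, abs=0.02)
        assert est.se > 0

    def test_nonpositive_bootstrap_count_rejected(self):
        h = make_hset([0.1, 0.2, 0.15], 0.01, [0.05, 0.1, 0.08], 0.01)
        with pytest.raises(DataError):
            mm.weighted_median(h, n_boot=0)

    def test_breakdown_point_resists_minority_corruption(self):
        # >50% of the weight on instruments with true ratio 0.4, the rest
        # corrupted upward: the weighted median stays near 0.4
        rng = np.random.default_rng(11)
        j = 21
        bx = rng.uniform(0.1, 0.3, j)
        sy = np.full(j, 0.004)
        by = 0.4 * bx + rng.normal(0, sy)
        by[:9] = 3.0 * bx[:9] + rng.normal(0, 0.004, 9)  # 9/21 corrupted
        est = mm.weighted_median(make_hset(bx, 0.002, by, sy), n_boot=500, seed=2)
        assert abs(est.beta - 0.4) < 3 * est.se + 0.03


class TestModeEstimators:
    def test_point_mass_returns_the_common_ratio(self):
        bx = np.array([0.1, 0.2, 0.4, 0.25])
        h = make_hset(bx, 0.01, 0.3 * bx, 0.01)
        est = mm.mode_estimate(h, weighted=True, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.3, abs=1e-6)

    def test_majority_cluster_beats_outliers(self):
        rng = np.random.default_rng(21)
        bx = rng.uniform(0.1, 0.3, 12)
        by = 0.5 * bx + rng.normal(0, 0.002, 12)
        by[-2:] = 3.0 * bx[-2:]  # two gross outliers
        est = mm.mode_estimate(make_hset(bx, 0.002, by, 0.004), n_boot=100, seed=3)
        assert abs(est.beta - 0.5) < 0.1

    def test_weighted_and_simple_agree_under_equal_weights(self):
        # identical bx, sx=0 and equal sy make the delta-method weights
        # exactly equal, so both variants see the same weighted density
        bx = np.full(6, 0.2)
        by = np.array([0.09, 0.1, 0.11, 0.1, 0.12, 0.08])
        h = make_hset(bx, 0.0, by, 0.01)
        w = mm.mode_estimate(h, weighted=True, n_boot=50, seed=5)
        s = mm.mode_estimate(h, weighted=False, n_boot=50, seed=5)
        assert w.beta == pytest.approx(s.beta, abs=1e-6)

    def test_zero_exposure_beta_excluded_with_warning(self):
        h = make_hset([0.0, 0.2, 0.15, 0.1], 0.01, [0.05, 0.1, 0.08, 0.05], 0.01)
        with pytest.warns(UserWarning, match="zero exposure beta"):
            est = mm.mode_estimate(h, n_boot=50, seed=1)
        assert est.n_snp == 3


class TestCochranQ:
    def test_hand_computed_two_residual_sum(self):
        # 3 SNPs, equal weights w=1/0.01²; slope from IVW, Q by hand
        bx = np.array([0.1, 0.2, 0.3])
        by = np.array([0.05, 0.11, 0.14])
        sy = np.full(3, 0.01)
        w = 1 / sy**2
        slope = np.sum(w * bx * by) / np.sum(w * bx * bx)
        q_hand = float(np.sum(w * (by - slope * bx) ** 2))
        res = mm.cochran_q(make_hset(bx, 0.01, by, sy), "ivw")
        assert res.q == pytest.approx(q_hand, rel=1e-12)
        assert res.df == 2

    def test_invariant_to_snp_relabeling(self):
        rng = np.random.default_rng(17)
        bx = rng.uniform(0.05, 0.3, 8)
        by = 0.4 * bx + rng.normal(0, 0.01, 8)
        h1 = make_hset(bx, 0.01, by, 0.01)
        perm = rng.permutation(8)
        h2 = make_hset(bx[perm], 0.01, by[perm], 0.01)
        for method in ("ivw", "egger"):
            assert mm.cochran_q(h1, method).q == pytest.approx(
                mm.cochran_q(h2, method).q, rel=1e-12
            )

    def test_degrees_of_freedom_per_method(self):
        h = make_hset([0.1, 0.2, 0.3, 0.15], 0.01, [0.04, 0.09, 0.13, 0.07], 0.01)
        assert mm.cochran_q(h, "ivw").df == 3
        assert mm.cochran_q(h, "egger").df == 2

    def test_too_few_snps_rejected(self):
        h = make_hset([0.1], 0.01, [0.05], 0.01)
        with pytest.raises(DataError):
            mm.cochran_q(h, "ivw")


class TestMrPresso:
    def _outlier_set(self, seed=0, j=20, displace=10.0):
        rng = np.random.default_rng(seed)
        maf = rng.uniform(0.05, 0.5, j)
        sx = 1 / np.sqrt(2 * maf * (1 - maf) * 1e5)
        sy = sx.copy()
        bx_true = rng.choice([-1, 1], j) * rng.uniform(8, 15, j) * sx
        bx = bx_true + rng.normal(0, sx)
        by = 0.3 * bx_true + rng.normal(0, sy)
        idx = int(rng.integers(0, j))
        by[idx] += displace * sy[idx]
        return make_hset(bx, sx, by, sy), f"rs{idx + 1}"

    def test_planted_outlier_flagged_and_accounting_holds(self):
        h, outlier = self._outlier_set(seed=5)
        res = mm.mr_presso(h, n_sim=1000, seed=1)
        assert outlier in res.outlier_rsids
        assert res.corrected_estimate.n_snp + len(res.outlier_rsids) == h.n_snp

    def test_clean_data_usually_yields_no_outliers(self):
        h, _ = self._outlier_set(seed=6, displace=0.0)
        res = mm.mr_presso(h, n_sim=1000, seed=2)
        assert res.outlier_rsids == []
        assert res.global_p > 0.05

    def test_too_few_snps_advises_plain_ivw(self):
        h = make_hset([0.1, 0.2, 0.3], 0.01, [0.05, 0.1, 0.14], 0.01)
        with pytest.raises(DataError, match="IVW"):
            mm.mr_presso(h)


class TestBhFdr:
    def test_identical_pvalues_unchanged(self):
        assert bh_fdr([0.02, 0.02, 0.02]) == pytest.approx([0.02, 0.02, 0.02])

    def test_stepup_on_arithmetic_sequence(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_empty_inputs(self):
        assert bh_fdr([0.37]) == [0.37]
        assert bh_fdr([]) == []

    def test_rejects_out_of_range(self):
        with pytest.raises(DataError):
            bh_fdr([0.1, 0.0])

    def test_monotone_nonincreasing_in_rank_and_capped(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(1e-6, 1, 50)
        adj = np.array(bh_fdr(p))
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestDirectionalConsistency:
    def _est(self, method, beta):
        return mm.MrEstimate(method, beta, 0.1, beta - 0.2, beta + 0.2, 0.05, 5)

    def test_all_same_sign_is_consistent(self):
        ests = [self._est(m, 0.4) for m in
                ("ivw", "egger", "weighted_median", "weighted_mode", "simple_mode")]
        ok, report = directional_consistency(ests)
        assert ok and report["consistent_with_ivw"].all()

    def test_opposite_sign_flags_inconsistency(self):
        ests = [self._est("ivw", 0.4), self._est("egger", -0.1)]
        ok, report = directional_consistency(ests)
        assert not ok
        assert not report.loc[report["method"] == "egger", "consistent_with_ivw"].item()

    def test_zero_beta_counts_as_consistent(self):
        ok, _ = directional_consistency([self._est("ivw", 0.4), self._est("egger", 0.0)])
        assert ok

    def test_missing_ivw_is_an_error(self):
        with pytest.raises(DataError):
            directional_consistency([self._est("egger", 0.1)])
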