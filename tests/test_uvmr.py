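"""Univariable estimators against closed-form and WLS oracles."""

import numpy as np
import pytest
import statsmodels.api as sm

from twostepmr import (
    InsufficientInstrumentsError,
    UnivariableMR,
    cochran_q,
    instrument_strength,
    ivw,
    leave_one_out,
    mr_egger,
    mr_presso,
    wald_ratios,
    weighted_median,
)
from twostepmr.simulate import SimulationConfig, harmonized_from_truth
from twostepmr.uvmr import weighted_median_point

from conftest import make_hset


class TestWaldRatios:
    def test_closed_form(self):
        h = make_hset([0.5], [0.01], [0.1], [0.05])
        wr = wald_ratios(h)
        assert wr["ratio"].iloc[0] == pytest.approx(0.2)
        assert wr["ratio_se"].iloc[0] == pytest.approx(0.1)

    def test_zero_outcome_beta_gives_zero_ratio(self):
        h = make_hset([0.5], [0.01], [0.0], [0.05])
        assert wald_ratios(h)["ratio"].iloc[0] == 0.0

    def test_zero_exposure_beta_flagged_invalid(self):
        h = make_hset([0.0, 0.5], [0.01, 0.01], [0.1, 0.1], [0.05, 0.05])
        wr = wald_ratios(h)
        assert not wr["valid"].iloc[0] and wr["valid"].iloc[1]

    def test_second_order_se_matches_numerical_delta_method(self, five_snp_hset):
        h = five_snp_hset
        wr = wald_ratios(h, second_order=True)
        bx, sx = h.beta_exp[:, 0], h.se_exp[:, 0]
        by, sy = h.beta_out, h.se_out
        eps = 1e-6
        # finite-difference gradient of f(bx, by) = by/bx
        d_bx = ((by / (bx + eps)) - (by / (bx - eps))) / (2 * eps)
        d_by = np.full_like(by, 1.0) / bx
        num_se = np.sqrt(d_bx**2 * sx**2 + d_by**2 * sy**2)
        np.testing.assert_allclose(wr["ratio_se"], num_se, rtol=1e-6)


class TestIVW:
    def test_single_snp_reduces_to_wald_ratio(self):
        h = make_hset([0.5], [0.01], [0.1], [0.05])
        fit = ivw(h, model="fixed")
        assert fit.estimate == pytest.approx(0.2)
        assert fit.se == pytest.approx(0.05 / 0.5)

    def test_homogeneous_ratios_give_zero_q_and_equal_ses(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_hset(bx, [0.01] * 3, 0.7 * bx, [0.02] * 3)
        fe = ivw(h, model="fixed")
        re = ivw(h, model="multiplicative-random")
        assert fe.estimate == pytest.approx(0.7)
        assert fe.q.q == pytest.approx(0.0, abs=1e-20)
        assert fe.se == pytest.approx(re.se)

    def test_matches_direct_summation_oracle(self, five_snp_hset):
        h = five_snp_hset
        w = 1.0 / h.se_out**2
        bx, by = h.beta_exp[:, 0], h.beta_out
        est = np.sum(w * bx * by) / np.sum(w * bx**2)
        se_fe = np.sum(w * bx**2) ** -0.5
        q = np.sum(w * (by - est * bx) ** 2)
        fit_fe = ivw(h, model="fixed")
        fit_re = ivw(h)
        assert fit_fe.estimate == pytest.approx(est, rel=1e-12)
        assert fit_fe.se == pytest.approx(se_fe, rel=1e-12)
        assert fit_re.q.q == pytest.approx(q, rel=1e-12)
        assert fit_re.se == pytest.approx(se_fe * max(1, np.sqrt(q / 4)), rel=1e-12)

    def test_equals_precision_weighted_mean_of_wald_ratios(self, five_snp_hset):
        h = five_snp_hset
        wr = wald_ratios(h)
        wts = h.beta_exp[:, 0] ** 2 / h.se_out**2
        assert ivw(h, model="fixed").estimate == pytest.approx(
            float(np.sum(wts * wr["ratio"]) / np.sum(wts)), rel=1e-12)

    def test_outcome_rescaling_equivariance(self, five_snp_hset):
        h = five_snp_hset
        k = 3.7
        h2 = make_hset(h.beta_exp[:, 0], h.se_exp[:, 0],
                       k * h.beta_out, k * h.se_out)
        f1, f2 = ivw(h), ivw(h2)
        assert f2.estimate == pytest.approx(k * f1.estimate, rel=1e-12)
        assert f2.zvalue == pytest.approx(f1.zvalue, rel=1e-12)

    def test_fixed_se_never_exceeds_random_se(self, rng):
        for _ in range(20):
            J = rng.integers(2, 15)
            h = make_hset(rng.uniform(0.05, 0.3, J), rng.uniform(0.005, 0.02, J),
                          rng.normal(0, 0.1, J), rng.uniform(0.005, 0.05, J))
            assert ivw(h, "fixed").se <= ivw(h).se + 1e-15


class TestEgger:
    def test_recovers_exact_line(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.05 + 0.3 * bx
        h = make_hset(bx, [0.01] * 4, by, [0.02] * 4)
        fit = mr_egger(h)
        assert fit.estimate == pytest.approx(0.3, rel=1e-10)
        assert fit.intercept == pytest.approx(0.05, rel=1e-10)
        assert fit.q.q == pytest.approx(0.0, abs=1e-18)

    def test_two_snps_insufficient(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)

    def test_matches_statsmodels_wls(self, rng):
        J = 10
        bx = rng.uniform(0.05, 0.3, J)
        by = 0.02 + 0.4 * bx + rng.normal(0, 0.03, J)
        sy = rng.uniform(0.01, 0.05, J)
        h = make_hset(bx, [0.01] * J, by, sy)
        fit = mr_egger(h)
        res = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert fit.estimate == pytest.approx(res.params[1], rel=1e-10)
        assert fit.intercept == pytest.approx(res.params[0], rel=1e-10)
        # statsmodels always scales by the residual dispersion; ours floors at 1
        disp = res.mse_resid
        expect_se = res.bse[1] / np.sqrt(disp) * np.sqrt(max(1.0, disp))
        assert fit.se == pytest.approx(expect_se, rel=1e-10)

    def test_orientation_invariance_of_slope(self, rng):
        J = 8
        bx = rng.uniform(0.05, 0.3, J) * rng.choice([-1, 1], J)
        by = 0.01 + 0.4 * bx + rng.normal(0, 0.02, J)
        h1 = make_hset(bx, [0.01] * J, by, [0.02] * J)
        flip = rng.choice([-1, 1], J)
        h2 = make_hset(bx * flip, [0.01] * J, by * flip, [0.02] * J)
        assert mr_egger(h1).estimate == pytest.approx(mr_egger(h2).estimate, rel=1e-12)


class TestWeightedMedian:
    def test_all_ratios_equal(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_hset(bx, [0.01] * 3, 0.5 * bx, [0.02] * 3)
        assert weighted_median(h, n_boot=50, seed=1).estimate == pytest.approx(0.5)

    def test_interpolation_formula_hand_example(self):
        # ratios 0.1..0.4 with equal weights: p_k = .125,.375,.625,.875,
        # crossing between the 2nd and 3rd -> 0.25
        est = weighted_median_point(np.array([0.1, 0.2, 0.3, 0.4]), np.ones(4))
        assert est == pytest.approx(0.25)

    def test_odd_count_equal_weights_is_middle_ratio(self):
        est = weighted_median_point(np.array([0.3, 0.1, 0.5]), np.ones(3))
        assert est == pytest.approx(0.3)

    def test_same_seed_gives_identical_se(self, five_snp_hset):
        a = weighted_median(five_snp_hset, n_boot=200, seed=42)
        b = weighted_median(five_snp_hset, n_boot=200, seed=42)
        assert a.se == b.se

    def test_insufficient_instruments(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.1, 0.1], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(h, seed=0)


class TestCochranQ:
    def test_homogeneous_is_zero_with_p_one(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_hset(bx, [0.01] * 3, 0.5 * bx, [0.02] * 3)
        qb = cochran_q(h, 0.5)
        assert qb.q == pytest.approx(0.0, abs=1e-18)
        assert qb.pvalue == pytest.approx(1.0)

    def test_matches_summation_oracle(self, five_snp_hset):
        h = five_snp_hset
        est = ivw(h, model="fixed").estimate
        wr = wald_ratios(h)
        expect = float(np.sum((1 / wr["ratio_se"] ** 2) * (wr["ratio"] - est) ** 2))
        assert cochran_q(h, est).q == pytest.approx(expect, rel=1e-12)

    def test_single_snp_undefined(self):
        h = make_hset([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q(h, 0.5)


class TestInstrumentStrength:
    def test_closed_form_and_zero(self):
        h = make_hset([0.1, 0.0], [0.01, 0.01], [0.1, 0.1], [0.02, 0.02])
        s = instrument_strength(h)
        assert s["per_snp"]["f_stat"].iloc[0] == pytest.approx(100.0)
        assert s["per_snp"]["f_stat"].iloc[1] == 0.0
        assert s["n_below_10"] == 1

    def test_mean_matches_direct_mean(self, rng):
        bx = rng.uniform(0.01, 0.2, 20)
        sx = rng.uniform(0.005, 0.02, 20)
        h = make_hset(bx, sx, rng.normal(0, 0.05, 20), [0.02] * 20)
        assert instrument_strength(h)["mean"] == pytest.approx(
            float(np.mean((bx / sx) ** 2)), rel=1e-12)


class TestLeaveOneOut:
    def test_two_snps_each_fit_is_other_wald_ratio(self):
        h = make_hset([0.2, 0.5], [0.01] * 2, [0.06, 0.2], [0.02] * 2)
        fits = leave_one_out(h)
        assert fits[0].estimate == pytest.approx(0.2 / 0.5)
        assert fits[1].estimate == pytest.approx(0.06 / 0.2)

    def test_homogeneous_instruments_all_equal_full_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_hset(bx, [0.01] * 4, 0.6 * bx, [0.02] * 4)
        full = ivw(h).estimate
        for f in leave_one_out(h):
            assert f.estimate == pytest.approx(full)

    def test_planted_outlier_causes_largest_shift_when_omitted(self, rng):
        J = 12
        bx = rng.uniform(0.1, 0.3, J)
        by = 0.4 * bx + rng.normal(0, 0.005, J)
        by[4] += 0.5  # gross pleiotropic outlier
        h = make_hset(bx, [0.01] * J, by, [0.02] * J)
        full = ivw(h).estimate
        shifts = [abs(f.estimate - full) for f in leave_one_out(h)]
        assert int(np.argmax(shifts)) == 4


class TestMRPresso:
    def test_requires_four_instruments(self):
        h = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.02] * 3)
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(h, seed=0)

    def test_null_data_clean_global_test(self):
        h, _ = harmonized_from_truth(SimulationConfig(
            J=30, pleio_mediator=(0, 0), pleio_outcome=(0, 0), seed=42))
        res = mr_presso(h, n_sim=1000, seed=1)
        assert res.global_p > 0.05
        assert res.outliers == []
        assert res.corrected_fit is None

    def test_planted_outlier_flagged_and_correction_helps(self):
        h, truth = harmonized_from_truth(SimulationConfig(
            J=30, pleio_mediator=(0, 0), pleio_outcome=(0, 0), seed=7))
        h.beta_out[3] += 15 * h.se_out[3]
        res = mr_presso(h, n_sim=1000, seed=2)
        assert h.snp_ids[3] in res.outliers
        assert res.global_p < 0.05
        truth_total = truth.total_effect
        assert (abs(res.corrected_fit.estimate - truth_total)
                < abs(res.raw_fit.estimate - truth_total))
        assert res.corrected_fit.method == "presso-corrected"

    def test_seed_determinism(self):
        h, _ = harmonized_from_truth(SimulationConfig(J=20, seed=9))
        a = mr_presso(h, n_sim=200, seed=5)
        b = mr_presso(h, n_sim=200, seed=5)
        assert a.global_p == b.global_p


class TestModelClass:
    def test_fit_dispatch_and_summary(self, five_snp_hset):
        model = UnivariableMR(five_snp_hset)
        fit = model.fit("ivw")
        assert "MR results" in fit.summary()
        assert model.fit("egger").method == "egger"
        assert len(model.funnel_data()) == 5

    def test_multi_exposure_set_rejected(self):
        h, _ = harmonized_from_truth(SimulationConfig(J=10, seed=1))
        import numpy as np
        h.beta_exp = np.hstack([h.beta_exp, h.beta_exp])
        h.se_exp = np.hstack([h.se_exp, h.se_exp])
        h.exposure_ids = ["X1", "X2"]
        h.exposure_scales = ["sd", "sd"]
        with pytest.raises(ValueError):
            UnivariableMR(h)
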