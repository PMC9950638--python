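"""MR estimators against closed-form oracles and their invariants."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st

from bidimr.errors import AnalysisError
from bidimr.estimators import (EggerEstimator, IVWEstimator,
                               MRPressoEstimator, WeightedMedianEstimator,
                               cochran_q, ivw, mr_egger, mr_presso,
                               wald_ratio, weighted_median)
from bidimr.sumstats import HarmonizedRecord


def _random_instance(rng, k=8):
    be = rng.normal(0.2, 0.1, k)
    be[np.abs(be) < 0.02] = 0.05
    se_e = rng.uniform(0.01, 0.05, k)
    bo = rng.normal(0.02, 0.05, k)
    se_o = rng.uniform(0.01, 0.08, k)
    return be, se_e, bo, se_o


def _hrec(beta_exp, beta_out, se_exp=0.02, se_out=0.01):
    return HarmonizedRecord(snp_id="rs1", beta_exp=beta_exp, se_exp=se_exp,
                            pval_exp=1e-8, beta_out=beta_out, se_out=se_out,
                            pval_out=0.05, n_exp=8000, n_out=8000)


class TestWaldRatio:
    def test_definition(self):
        est = wald_ratio(_hrec(0.1, 0.02, se_out=0.01))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        assert wald_ratio(_hrec(0.1, 0.0)).beta == 0.0

    def test_negative_exposure_effect_flips_sign(self):
        assert wald_ratio(_hrec(-0.1, 0.02)).beta == pytest.approx(-0.2)

    def test_null_instrument_is_error(self):
        with pytest.raises(AnalysisError, match="null instrument"):
            wald_ratio(_hrec(0.0, 0.02))

    def test_second_order_se_is_larger(self):
        first = wald_ratio(_hrec(0.1, 0.05))
        second = wald_ratio(_hrec(0.1, 0.05), second_order=True)
        assert second.se > first.se


class TestIVW:
    def test_equal_ratios_degenerate(self):
        be = np.array([0.1, 0.2, 0.4])
        est_f = ivw((be, be / 5, 0.1 * be, np.full(3, 0.01)), model="fixed")
        est_m = ivw((be, be / 5, 0.1 * be, np.full(3, 0.01)), model="mre")
        assert est_f.beta == pytest.approx(0.1)
        assert est_f.Q == pytest.approx(0.0, abs=1e-20)
        assert est_f.I2 == 0.0
        assert est_m.se == pytest.approx(est_f.se)

    def test_two_snp_worked_example(self):
        # gamma=(0.1,0.2), Gamma=(0.02,0.02), se_out=0.01: weights 100, 400
        est = ivw(([0.1, 0.2], [0.01, 0.01], [0.02, 0.02], [0.01, 0.01]),
                  model="fixed")
        assert est.beta == pytest.approx(0.12)
        assert est.se == pytest.approx(1 / np.sqrt(500))

    def test_single_snp_equals_wald(self):
        rec = _hrec(0.1, 0.02, se_out=0.01)
        est = ivw(([0.1], [0.02], [0.02], [0.01]))
        wald = wald_ratio(rec)
        assert est.beta == pytest.approx(wald.beta)
        assert est.se == pytest.approx(wald.se)

    def test_matches_wls_oracle(self, rng):
        for _ in range(50):
            be, se_e, bo, se_o = _random_instance(rng)
            est = ivw((be, se_e, bo, se_o), model="fixed")
            fit = sm.WLS(bo, be, weights=1.0 / se_o ** 2).fit()
            assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
            # fixed-effect SE: unscaled WLS standard error
            assert est.se == pytest.approx(
                float(fit.bse[0] / np.sqrt(fit.scale)), abs=1e-10)

    def test_mre_se_never_below_fixed(self, rng):
        for _ in range(50):
            be, se_e, bo, se_o = _random_instance(rng)
            fixed = ivw((be, se_e, bo, se_o), model="fixed")
            mre = ivw((be, se_e, bo, se_o), model="mre")
            assert mre.se >= fixed.se - 1e-15

    def test_joint_sign_flip_invariance(self, rng):
        be, se_e, bo, se_o = _random_instance(rng)
        flip = rng.choice([1.0, -1.0], size=be.size)
        a = ivw((be, se_e, bo, se_o))
        b = ivw((be * flip, se_e, bo * flip, se_o))
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.Q == pytest.approx(b.Q, abs=1e-9)

    def test_empty_is_error(self):
        with pytest.raises(AnalysisError):
            ivw(([], [], [], []))


class TestEgger:
    def test_exact_linear_pleiotropy_recovered(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.4])
        Gamma = 0.05 + 0.3 * gamma
        est = mr_egger((gamma, gamma / 10, Gamma, np.full(4, 0.01)))
        assert est.intercept == pytest.approx(0.05, abs=1e-12)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.Q == pytest.approx(0.0, abs=1e-18)

    def test_no_pleiotropy_zero_intercept(self):
        gamma = np.array([0.1, 0.25, 0.4])
        est = mr_egger((gamma, gamma / 10, 0.2 * gamma, np.full(3, 0.02)))
        assert est.intercept == pytest.approx(0.0, abs=1e-14)

    def test_matches_wls_oracle(self, rng):
        for _ in range(50):
            be, se_e, bo, se_o = _random_instance(rng)
            flip = np.where(be < 0, -1.0, 1.0)
            x, y = be * flip, bo * flip
            fit = sm.WLS(y, sm.add_constant(x), weights=1.0 / se_o ** 2).fit()
            est = mr_egger((be, se_e, bo, se_o))
            assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
            assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
            scale = max(1.0, float(fit.scale))  # over-dispersion floor at 1
            oracle_se = float(fit.bse[1] / np.sqrt(fit.scale) * np.sqrt(scale))
            assert est.se == pytest.approx(oracle_se, abs=1e-10)

    def test_joint_sign_flip_invariance(self, rng):
        be, se_e, bo, se_o = _random_instance(rng)
        flip = rng.choice([1.0, -1.0], size=be.size)
        a = mr_egger((be, se_e, bo, se_o))
        b = mr_egger((be * flip, se_e, bo * flip, se_o))
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-12)

    def test_zero_intercept_constraint_reproduces_ivw(self, rng):
        # constrained refit: WLS without intercept is exactly the IVW slope
        be, se_e, bo, se_o = _random_instance(rng)
        constrained = sm.WLS(bo, be, weights=1.0 / se_o ** 2).fit()
        est = ivw((be, se_e, bo, se_o), model="fixed")
        assert est.beta == pytest.approx(constrained.params[0], abs=1e-12)

    def test_too_few_instruments(self):
        with pytest.raises(AnalysisError, match="Egger"):
            mr_egger(([0.1, 0.2], [0.01, 0.01], [0.01, 0.02], [0.01, 0.01]))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        est = weighted_median(([1.0, 1.0, 1.0], [0.1] * 3,
                               [0.1, 0.2, 0.9], [1.0] * 3), n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_hand_interpolation_oracle(self):
        # ratios (1,2,3) with weights (4,1,1): cumulative midpoints
        # (1/3, 3/4, 11/12); interpolating 0.5 gives 1.4
        be = np.array([2.0, 1.0, 1.0])
        bo = np.array([2.0, 2.0, 3.0])     # ratios 1, 2, 3
        se_o = np.array([1.0, 1.0, 1.0])   # weights be^2 = 4, 1, 1
        est = weighted_median((be, 0.1 * be, bo, se_o), n_boot=50, seed=1)
        assert est.beta == pytest.approx(1.4)

    def test_identical_ratios_returned_exactly(self):
        be = np.array([0.1, 0.2, 0.3, 0.4])
        est = weighted_median((be, be / 10, 0.7 * be, np.full(4, 0.01)),
                              n_boot=200, seed=3)
        assert est.beta == pytest.approx(0.7)
        assert est.se < 0.2

    @given(k=st.sampled_from([3, 5, 7, 9]), seed=st.integers(0, 100))
    def test_equal_weights_odd_k_equals_sample_median(self, k, seed):
        rng = np.random.default_rng(seed)
        ratios = rng.normal(0.2, 0.5, k)
        be = np.ones(k)
        est = weighted_median((be, 0.01 * be, ratios, np.ones(k)),
                              n_boot=10, seed=0)
        assert est.beta == pytest.approx(np.median(ratios), abs=1e-12)

    def test_bootstrap_se_reproducible(self):
        data = ([0.1, 0.2, 0.3], [0.01] * 3, [0.02, 0.03, 0.02], [0.01] * 3)
        a = weighted_median(data, n_boot=200, seed=42)
        b = weighted_median(data, n_boot=200, seed=42)
        assert a.se == b.se


class TestCochranQ:
    def test_identical_estimates(self):
        Q, df, pval, i2 = cochran_q([(0.1, 0.05), (0.1, 0.05), (0.1, 0.05)])
        assert Q == pytest.approx(0.0) and i2 == 0.0 and pval == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        Q, df, pval, i2 = cochran_q([(0.0, 1.0), (2.0, 1.0)])
        assert Q == pytest.approx(2.0) and df == 1

    def test_simulated_heterogeneity_recovers_i2(self, rng):
        # tau2 = 3 * within-variance gives expected I2 = 0.75
        k, tau = 600, np.sqrt(3.0)
        b = rng.normal(0, 1.0, k) * tau + rng.normal(0, 1.0, k)
        _, _, _, i2 = cochran_q([(float(x), 1.0) for x in b])
        assert i2 == pytest.approx(0.75, abs=0.05)

    def test_single_estimate_is_error(self):
        with pytest.raises(AnalysisError):
            cochran_q([(0.1, 0.05)])


class TestPresso:
    def test_too_few_instruments(self):
        with pytest.raises(AnalysisError, match="PRESSO"):
            mr_presso(([0.1] * 3, [0.01] * 3, [0.02] * 3, [0.01] * 3))

    def test_planted_outlier_detected(self, rng):
        k = 20
        be = rng.normal(0.25, 0.05, k)
        se_e = np.full(k, 0.017)
        se_o = np.full(k, 0.017)
        bo = rng.normal(0.1 * be, se_o)
        bo[7] += 10 * se_o[7]              # residual inflated by 10 outcome SEs
        res = mr_presso((be, se_e, bo, se_o), n_sim=1000, seed=5)
        assert res.global_pval <= 0.01
        assert "7" in {s for s, _ in res.outlier_snps}
        assert res.corrected is not None
        assert abs(res.corrected.beta - 0.1) < abs(res.raw.beta - 0.1)

    def test_null_type_one_error_controlled(self):
        from bidimr.simulate import scenario, simulate_arrays
        rej = 0
        n_rep = 250
        for i in range(n_rep):
            be, se_e, bo, se_o = simulate_arrays(scenario("null"), seed=700_000 + i)
            rej += mr_presso((be, se_e, bo, se_o), n_sim=500, seed=i).global_pval < 0.05
        assert rej / n_rep <= 0.07

    def test_seeded_determinism(self, rng):
        data = _random_instance(rng)
        a = mr_presso(data, n_sim=300, seed=9)
        b = mr_presso(data, n_sim=300, seed=9)
        assert a.global_pval == b.global_pval


class TestSklearnInterface:
    def test_get_set_params_and_fit(self, rng):
        from sklearn.base import clone
        be, se_e, bo, se_o = _random_instance(rng)
        est = IVWEstimator(model="fixed")
        assert clone(est).get_params()["model"] == "fixed"
        est.fit((be, se_e, bo, se_o))
        assert hasattr(est, "beta_") and est.n_snp_ == be.size
        assert est.estimate_.method == "ivw_fe"

    def test_egger_estimator_exposes_intercept(self, rng):
        est = EggerEstimator().fit(_random_instance(rng))
        assert est.intercept_pval_ > 0

    def test_weighted_median_estimator_seeded(self, rng):
        data = _random_instance(rng)
        a = WeightedMedianEstimator(n_boot=100, random_state=4).fit(data)
        b = WeightedMedianEstimator(n_boot=100, random_state=4).fit(data)
        assert a.se_ == b.se_

    def test_presso_estimator_result(self, rng):
        est = MRPressoEstimator(n_sim=200, random_state=2).fit(_random_instance(rng))
        assert 0 < est.global_pval_ <= 1

    def test_predict_applies_slope(self, rng):
        est = IVWEstimator().fit(_random_instance(rng))
        x = np.array([0.0, 1.0])
        assert est.predict(x)[1] == pytest.approx(est.beta_)

    def test_coverage_of_true_effect(self):
        # parameter recovery across methods on clean synthetic data
        from bidimr.simulate import scenario, simulate_arrays
        n_rep, theta = 120, 0.1
        hits = {"ivw": 0, "egger": 0, "wm": 0}
        for i in range(n_rep):
            data = simulate_arrays(scenario("causal"), seed=800_000 + i)
            e1 = ivw(data)
            e2 = mr_egger(data)
            e3 = weighted_median(data, n_boot=200, seed=i)
            hits["ivw"] += e1.ci_low <= theta <= e1.ci_high
            hits["egger"] += e2.ci_low <= theta <= e2.ci_high
            hits["wm"] += e3.ci_low <= theta <= e3.ci_high
        for method, h in hits.items():
            assert h / n_rep >= 0.90, method
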