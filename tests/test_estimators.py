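"""Estimator suite: Wald ratios, IVW, Egger, weighted median, LOO, Steiger."""

import numpy as np
import pytest
import statsmodels.api as sm

from mrscreen.estimators import (
    cochran_q,
    egger,
    ivw,
    leave_one_out,
    steiger,
    wald_ratios,
    weighted_median,
    weighted_median_point,
)
from mrscreen.simulate import ScenarioTruth, simulate_harmonized

from conftest import make_harmonized


class TestWaldRatios:
    def test_direct_division_and_se(self):
        h = make_harmonized([0.1], [0.2], se_y=[0.05])
        r, s = wald_ratios(h)
        assert r[0] == pytest.approx(2.0) and s[0] == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        r, _ = wald_ratios(make_harmonized([0.1], [0.0]))
        assert r[0] == 0.0

    def test_negative_gamma_sign(self):
        h = make_harmonized([-0.1], [0.2], se_y=[0.05])
        r, s = wald_ratios(h)
        assert r[0] == pytest.approx(-2.0) and s[0] == pytest.approx(0.5)

    def test_zero_gamma_names_snp(self):
        with pytest.raises(ValueError, match="rs0002"):
            wald_ratios(make_harmonized([0.1, 0.0], [0.2, 0.1]))


class TestIVW:
    def test_homogeneous_ratios_give_exact_beta_and_zero_q(self):
        h = make_harmonized([0.1, 0.2, 0.4], [0.05, 0.1, 0.2])
        res, het = ivw(h)
        assert res.beta == pytest.approx(0.5, abs=1e-14)
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.i2 == 0.0
        assert res.method == "ivw_fixed"

    def test_closed_form_two_snp_example(self):
        h = make_harmonized([0.1, 0.2], [0.1, 0.2], se_y=[0.05, 0.05])
        res, _ = ivw(h)
        assert res.beta == pytest.approx(1.0, abs=1e-14)

    def test_matches_wls_oracle(self):
        h = make_harmonized([0.1, 0.25, 0.4], [0.03, 0.02, 0.1],
                            se_y=[0.05, 0.03, 0.08])
        res, het = ivw(h, model="fixed")
        w = 1.0 / h.se_y**2
        fit = sm.WLS(h.Gamma, h.gamma, weights=w).fit()
        assert res.beta == pytest.approx(fit.params[0], abs=1e-10)
        assert res.se == pytest.approx(float(fit.bse[0] / np.sqrt(fit.scale)), abs=1e-10)
        assert het.Q == pytest.approx(float(fit.ssr), abs=1e-10)

    def test_single_instrument_degrades_to_wald(self):
        res, het = ivw(make_harmonized([0.1], [0.2], se_y=[0.05]))
        assert res.method == "wald_ratio"
        assert res.beta == pytest.approx(2.0) and res.se == pytest.approx(0.5)
        assert het.df == 0

    def test_random_effects_inflates_se_only_under_heterogeneity(self):
        rng = np.random.default_rng(5)
        gamma = rng.uniform(0.05, 0.2, 12)
        Gamma = 0.3 * gamma + rng.normal(0, 0.05, 12)  # gross overdispersion
        h = make_harmonized(gamma, Gamma, se_y=np.full(12, 0.005))
        res_auto, het = ivw(h, model="auto")
        res_fixed, _ = ivw(h, model="fixed")
        assert het.pval < 0.05 and het.i2 > 25
        assert res_auto.method == "ivw_random"
        assert res_auto.se == pytest.approx(
            res_fixed.se * np.sqrt(het.Q / het.df), rel=1e-12
        )
        assert res_auto.beta == res_fixed.beta

    def test_q_invariant_to_instrument_order(self, rng):
        h, _ = simulate_harmonized(ScenarioTruth(causal_beta=0.1, k_snps=15, seed=3))
        perm = rng.permutation(h.k)
        hp = make_harmonized(h.gamma[perm], h.Gamma[perm],
                             se_x=h.se_x[perm], se_y=h.se_y[perm])
        _, het = ivw(h)
        _, hetp = ivw(hp)
        assert het.Q == pytest.approx(hetp.Q, rel=1e-12)
        assert 0 <= het.i2 < 100


class TestEgger:
    def test_exact_linear_data_recovered_to_machine_precision(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.5])
        h = make_harmonized(gamma, 0.02 + 0.4 * gamma)
        res, pleio = egger(h)
        assert res.beta == pytest.approx(0.4, abs=1e-12)
        assert pleio.intercept == pytest.approx(0.02, abs=1e-12)

    def test_matches_wls_oracle_with_intercept(self):
        gamma = np.array([0.08, 0.15, 0.22, 0.41])
        Gamma = np.array([0.05, 0.02, 0.11, 0.13])
        se_y = np.array([0.01, 0.02, 0.015, 0.012])
        h = make_harmonized(gamma, Gamma, se_y=se_y)
        res, pleio = egger(h)
        X = sm.add_constant(gamma)
        fit = sm.WLS(Gamma, X, weights=1 / se_y**2).fit()
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert pleio.intercept == pytest.approx(fit.params[0], abs=1e-10)
        if fit.scale >= 1:  # dispersion floor does not bind here
            assert res.se == pytest.approx(float(fit.bse[1]), abs=1e-10)
            assert pleio.se == pytest.approx(float(fit.bse[0]), abs=1e-10)

    def test_orientation_makes_result_flip_invariant(self):
        gamma = np.array([0.1, -0.2, 0.3, -0.4, 0.25])
        Gamma = 0.3 * gamma + np.array([0.01, -0.02, 0.015, 0.0, -0.01])
        h1 = make_harmonized(gamma, Gamma)
        h2 = make_harmonized(-gamma, -Gamma)
        r1, p1 = egger(h1)
        r2, p2 = egger(h2)
        assert r1.beta == pytest.approx(r2.beta, rel=1e-12)
        assert p1.intercept == pytest.approx(p2.intercept, rel=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError, match="3 instruments"):
            egger(make_harmonized([0.1, 0.2], [0.1, 0.2]))


class TestWeightedMedian:
    def test_equal_weights_reduce_to_plain_median(self):
        h = make_harmonized([0.1, 0.1, 0.1], [0.1, 0.2, 0.9])
        assert weighted_median_point(h) == pytest.approx(2.0)

    def test_dominant_weight_returns_its_ratio(self):
        # middle SNP carries 60% of the weight, flanked symmetrically
        gamma = np.array([np.sqrt(0.2), np.sqrt(0.6), np.sqrt(0.2)])
        h = make_harmonized(gamma, gamma * np.array([1.0, 2.0, 3.0]))
        assert weighted_median_point(h) == pytest.approx(2.0)

    def test_hand_instance_matches_interp_oracle(self, rng):
        for _ in range(20):
            gamma = rng.uniform(0.05, 0.3, 5)
            Gamma = rng.normal(0, 0.05, 5)
            se_y = rng.uniform(0.005, 0.02, 5)
            h = make_harmonized(gamma, Gamma, se_y=se_y)
            ratios = Gamma / gamma
            w = gamma**2 / se_y**2
            order = np.argsort(ratios)
            v, ww = ratios[order], w[order] / w.sum()
            s = np.cumsum(ww) - 0.5 * ww
            expected = float(np.interp(0.5, s, v))
            assert weighted_median_point(h) == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_se_deterministic_under_seed(self):
        h, _ = simulate_harmonized(ScenarioTruth(causal_beta=0.2, k_snps=10, seed=8))
        r1 = weighted_median(h, n_boot=200, seed=11)
        r2 = weighted_median(h, n_boot=200, seed=11)
        assert r1.se == r2.se and r1.beta == r2.beta

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            weighted_median(make_harmonized([0.1, 0.2], [0.1, 0.2]))


class TestLeaveOneOut:
    def test_homogeneous_rows_equal_full_estimate(self):
        h = make_harmonized([0.1, 0.2, 0.4, 0.3], [0.05, 0.1, 0.2, 0.15])
        full, _ = ivw(h)
        loo = leave_one_out(h)
        assert len(loo) == 4
        np.testing.assert_allclose(loo["beta"], full.beta, atol=1e-12)

    def test_gross_outlier_has_largest_influence(self):
        gamma = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        Gamma = 0.3 * gamma
        Gamma[2] += 0.2  # gross outlier
        h = make_harmonized(gamma, Gamma)
        loo = leave_one_out(h)
        worst = loo.loc[loo["delta_beta"].abs().idxmax(), "dropped_snp"]
        assert worst == h.snp_ids[2]

    def test_three_rows_for_three_instruments(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.03, 0.06, 0.09])
        assert len(leave_one_out(h)) == 3


class TestSteiger:
    def test_strong_exposure_signal_supports_direction(self):
        h, _ = simulate_harmonized(ScenarioTruth(causal_beta=0.2, seed=4))
        res = steiger(h)
        assert res.direction_correct
        assert res.pval < 0.001
        assert 0 <= res.r2_outcome < res.r2_exposure < 1

    def test_identical_inputs_symmetric(self):
        h = make_harmonized([0.1, 0.2, 0.3], [0.1, 0.2, 0.3],
                            se_x=[0.01] * 3, se_y=[0.01] * 3, n_exp=5000, n_out=5000)
        res = steiger(h)
        assert not res.direction_correct
        assert res.pval == pytest.approx(1.0)

    def test_swapping_sides_negates_direction_same_p(self):
        h, _ = simulate_harmonized(ScenarioTruth(causal_beta=0.2, seed=4))
        fwd = steiger(h)
        swapped = make_harmonized(h.Gamma, h.gamma, se_x=h.se_y, se_y=h.se_x,
                                  n_exp=h.n_out, n_out=h.n_exp)
        rev = steiger(swapped)
        assert rev.direction_correct != fwd.direction_correct
        assert rev.pval == pytest.approx(fwd.pval, rel=1e-12)


class TestSharedProperties:
    def test_allele_flip_invariance_of_all_estimators(self, rng):
        h, _ = simulate_harmonized(ScenarioTruth(causal_beta=0.15, k_snps=12, seed=9))
        flip = rng.choice([1.0, -1.0], size=h.k)
        hf = make_harmonized(h.gamma * flip, h.Gamma * flip,
                             se_x=h.se_x, se_y=h.se_y)
        assert ivw(hf)[0].beta == pytest.approx(ivw(h)[0].beta, rel=1e-12)
        assert egger(hf)[0].beta == pytest.approx(egger(h)[0].beta, rel=1e-12)
        assert weighted_median_point(hf) == pytest.approx(
            weighted_median_point(h), rel=1e-12
        )

    def test_outcome_scale_equivariance(self):
        h, _ = simulate_harmonized(ScenarioTruth(causal_beta=0.15, k_snps=12, seed=9))
        c = 3.7
        hs = make_harmonized(h.gamma, c * h.Gamma, se_x=h.se_x, se_y=c * h.se_y)
        assert ivw(hs)[0].beta == pytest.approx(c * ivw(h)[0].beta, rel=1e-12)
        assert egger(hs)[0].beta == pytest.approx(c * egger(h)[0].beta, rel=1e-12)
        assert weighted_median_point(hs) == pytest.approx(
            c * weighted_median_point(h), rel=1e-12
        )

    def test_cochran_q_identity_between_ivw_and_helper(self):
        h, _ = simulate_harmonized(ScenarioTruth(causal_beta=0.1, k_snps=8, seed=2))
        res, het = ivw(h, model="fixed")
        het2 = cochran_q(h, res.beta)
        assert het.Q == pytest.approx(het2.Q, rel=1e-12)
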