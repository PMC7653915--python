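import numpy as np
import pytest

from summr.datatypes import InputError, MRResult
from summr.svmr import (SingleVariableMR, _weighted_median, _weighted_mode,
                        as_odds_ratio, egger, ivw, wald_ratio, weighted_median,
                        weighted_mode)


class TestWaldRatio:
    def test_simple_division(self):
        assert np.isclose(wald_ratio(0.1, 0.01, 0.05, 0.01).estimate, 0.5)

    def test_zero_outcome_beta(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.01).estimate == 0.0

    def test_first_order_se(self):
        r = wald_ratio(0.2, 0.01, 0.04, 0.01)
        assert np.isclose(r.estimate, 0.2)
        assert np.isclose(r.se, 0.05)

    def test_zero_exposure_beta_errors(self):
        with pytest.raises(InputError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


class TestIvw:
    def test_homogeneous_ratios(self, make_harmonized):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, bx * 0 + 0.01, 0.2 * bx, [0.01, 0.02, 0.03])
        r = ivw(h)
        assert np.isclose(r.estimate, 0.2)
        assert np.isclose(r.q_statistic, 0.0, atol=1e-20)

    def test_closed_form_two_snps(self, make_harmonized):
        # w1 = 1e4, w2 = 2500: (30 + 25) / (100 + 100) = 0.275
        h = make_harmonized([0.1, 0.2], [0.01, 0.01], [0.03, 0.05],
                            [0.01, 0.02])
        assert np.isclose(ivw(h).estimate, 0.275, atol=1e-12)

    def test_fewer_than_two_snps_errors(self, make_harmonized):
        h = make_harmonized([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(InputError, match="wald_ratio"):
            ivw(h)

    def test_random_effects_never_shrink_se(self, make_harmonized):
        rng = np.random.default_rng(0)
        h = make_harmonized(rng.normal(0.1, 0.02, 20), np.full(20, 0.005),
                            rng.normal(0.02, 0.02, 20), np.full(20, 0.01))
        assert ivw(h, "multiplicative_random").se >= ivw(h, "fixed").se - 1e-15

    @pytest.mark.parametrize("seed", [0, 1, 7, 42, 123, 2**30])
    def test_order_and_negation_invariance(self, seed, make_harmonized):
        rng = np.random.default_rng(seed)
        k = 8
        bx = rng.normal(0.1, 0.05, k)
        by = rng.normal(0.02, 0.02, k)
        byse = rng.uniform(0.005, 0.02, k)
        h = make_harmonized(bx, np.full(k, 0.01), by, byse)
        base = ivw(h).estimate
        perm = rng.permutation(k)
        h_perm = make_harmonized(bx[perm], np.full(k, 0.01), by[perm],
                                 byse[perm])
        assert np.isclose(ivw(h_perm).estimate, base, atol=1e-12)
        flip = np.where(rng.random(k) < 0.5, -1, 1)
        h_flip = make_harmonized(bx * flip, np.full(k, 0.01), by * flip, byse)
        assert np.isclose(ivw(h_flip).estimate, base, atol=1e-12)


class TestEgger:
    def test_exact_linear_fit_recovered(self, make_harmonized):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        by = 0.01 + 0.3 * bx
        h = make_harmonized(bx, np.full(4, 0.01), by, np.full(4, 0.01))
        r = egger(h)
        assert np.isclose(r.estimate, 0.3, atol=1e-10)
        assert np.isclose(r.intercept, 0.01, atol=1e-10)

    def test_orientation_makes_bx_nonnegative(self, make_harmonized):
        # jointly negating a SNP must not change the Egger fit
        bx = np.array([0.05, -0.1, 0.2, 0.3])
        by = 0.01 * np.sign(bx) + 0.3 * bx
        h = make_harmonized(bx, np.full(4, 0.01), by, np.full(4, 0.01))
        h2 = make_harmonized(np.abs(bx), np.full(4, 0.01), by * np.sign(bx),
                             np.full(4, 0.01))
        assert np.isclose(egger(h).estimate, egger(h2).estimate, atol=1e-12)
        assert np.isclose(egger(h).intercept, egger(h2).intercept, atol=1e-12)

    def test_agrees_with_statsmodels_wls(self, make_harmonized):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        k = 25
        bx = np.abs(rng.normal(0.1, 0.03, k))
        byse = rng.uniform(0.005, 0.02, k)
        by = 0.005 + 0.25 * bx + rng.normal(0, 0.01, k)
        h = make_harmonized(bx, np.full(k, 0.01), by, byse)
        r = egger(h)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / byse**2).fit()
        assert np.isclose(r.estimate, fit.params[1], atol=1e-10)
        assert np.isclose(r.intercept, fit.params[0], atol=1e-10)
        # with sigma floored at 1 and Q/(k-2) > 1 here, SEs match WLS's
        sigma2 = r.q_statistic / (k - 2)
        if sigma2 >= 1:
            assert np.isclose(r.se, fit.bse[1], rtol=1e-8)

    def test_needs_three_snps(self, make_harmonized):
        h = make_harmonized([0.1, 0.2], [0.01] * 2, [0.02, 0.04], [0.01] * 2)
        with pytest.raises(InputError):
            egger(h)


class TestWeightedMedian:
    def test_equal_weight_interpolation(self, make_harmonized):
        assert np.isclose(
            _weighted_median(np.array([0.1, 0.2, 0.3]), np.ones(3)), 0.2)

    def test_all_ratios_equal(self, make_harmonized):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(bx, np.full(3, 0.01), 0.7 * bx, np.full(3, 0.01))
        r = weighted_median(h, n_boot=200, seed=0)
        assert np.isclose(r.estimate, 0.7)
        assert r.se > 0

    def test_dominant_weight_returns_that_ratio(self):
        ratios = np.array([0.1, 0.5, 0.9])
        weights = np.array([1e-6, 1e6, 1e-6])
        assert np.isclose(_weighted_median(ratios, weights), 0.5, atol=1e-3)

    def test_deterministic_given_seed(self, make_harmonized):
        rng = np.random.default_rng(0)
        bx = rng.normal(0.1, 0.02, 10)
        h = make_harmonized(bx, np.full(10, 0.01),
                            0.3 * bx + rng.normal(0, 0.01, 10),
                            np.full(10, 0.01))
        a = weighted_median(h, n_boot=100, seed=7)
        b = weighted_median(h, n_boot=100, seed=7)
        assert a.estimate == b.estimate and a.se == b.se


class TestWeightedMode:
    def test_cluster_mode_found(self):
        # brute-force oracle: the density argmax must be within one
        # bandwidth of the dominant cluster at 0.2
        ratios = np.array([0.20, 0.20, 0.21, 0.80])
        weights = np.ones(4)
        est = _weighted_mode(ratios, weights)
        sd = np.std(ratios, ddof=1)
        mad = np.median(np.abs(ratios - np.median(ratios))) * 1.4826
        h = 0.9 * min(sd, mad) * 4 ** (-0.2)
        assert abs(est - 0.2) < h

    def test_degenerate_mode(self, make_harmonized):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonized(bx, np.full(3, 0.01), 0.45 * bx, np.full(3, 0.01))
        assert np.isclose(weighted_mode(h, n_boot=50, seed=0).estimate, 0.45)

    def test_bandwidth_multiplier_widens_smoothing(self):
        ratios = np.array([0.1, 0.12, 0.14, 0.5, 0.52])
        weights = np.ones(5)
        est_narrow = _weighted_mode(ratios, weights, phi=0.5)
        assert 0.05 < est_narrow < 0.2


class TestOddsRatioConversion:
    def test_headline_conversion(self):
        # log-odds -0.646 with CI (-0.887, -0.406) -> OR 0.524 (0.412, 0.666)
        r = MRResult("ivw", -0.646, 0.123, -0.887, -0.406, 1e-7, 100,
                     outcome_type="binary")
        o, lo, hi = as_odds_ratio(r)
        assert (round(o, 3), round(lo, 3), round(hi, 3)) == (0.524, 0.412, 0.666)

    def test_null_and_doubling(self):
        r = MRResult("ivw", 0.0, 0.1, -0.1, 0.1, 0.9, 10)
        assert np.isclose(as_odds_ratio(r)[0], 1.0)
        r2 = MRResult("ivw", np.log(2), 0.1, 0.0, 1.0, 0.01, 10)
        assert np.isclose(as_odds_ratio(r2)[0], 2.0)

    def test_continuous_outcome_rejected(self):
        r = MRResult("ivw", 0.5, 0.1, 0.3, 0.7, 0.01, 10,
                     outcome_type="continuous")
        with pytest.raises(InputError, match="beta"):
            as_odds_ratio(r)


class TestModelObject:
    def test_fit_dispatch_and_unknown_method(self, make_harmonized):
        bx = np.linspace(0.05, 0.3, 6)
        h = make_harmonized(bx, np.full(6, 0.01), 0.2 * bx, np.full(6, 0.01))
        m = SingleVariableMR(h)
        assert np.isclose(m.fit("ivw").estimate, 0.2)
        with pytest.raises(InputError, match="unknown method"):
            m.fit("mr_lasso")

    def test_multi_exposure_set_rejected(self, make_harmonized):
        h = make_harmonized([[0.1, 0.2], [0.2, 0.1], [0.3, 0.3]],
                            [[0.01] * 2] * 3, [0.02, 0.04, 0.06],
                            [0.01] * 3)
        with pytest.raises(InputError, match="MultivariableMR"):
            SingleVariableMR(h)

    def test_summary_renders(self, make_harmonized):
        bx = np.linspace(0.05, 0.3, 6)
        h = make_harmonized(bx, np.full(6, 0.01), 0.2 * bx, np.full(6, 0.01))
        text = SingleVariableMR(h).fit_ivw().summary()
        assert "OR" in text and "Cochran Q" in text
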