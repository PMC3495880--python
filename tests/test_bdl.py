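"""Birth-death likelihood suite: formulas, nesting, fitting, AIC."""

import math

import numpy as np
import pytest

from macrodiv.bdl import (DiversificationFit, BDLModel, fit_bdl_suite,
                          fit_purebirth, fit_bd, fit_density_dependent,
                          fit_yule_multirate, loglik_purebirth, loglik_bd,
                          loglik_density_dependent, loglik_yule_multirate,
                          delta_aic_significance)
from macrodiv.simulate import simulate_yule, simulate_bd, \
    simulate_multirate_yule
from macrodiv.tree import internode_intervals


class TestPureBirth:
    def test_hand_value(self):
        # n = 3, g = (1,1), lam = 0.2: ln 2 + ln 0.2 - 1
        assert loglik_purebirth([1, 1], 0.2) == pytest.approx(-1.916291,
                                                              abs=1e-6)

    def test_closed_form_mle(self):
        fit = fit_purebirth([1.0, 1.0])
        assert fit.params["r1"] == pytest.approx(0.2)

    def test_mle_agrees_with_numeric_optimum(self, yule_trees):
        from scipy.optimize import minimize_scalar
        for t in yule_trees[:4]:
            g = t.internode_intervals()
            lam_hat = fit_purebirth(g).params["r1"]
            res = minimize_scalar(
                lambda ll: -loglik_purebirth(g, math.exp(ll)),
                bounds=(-8, 8), method="bounded",
                options={"xatol": 1e-12})
            assert lam_hat == pytest.approx(math.exp(res.x), rel=1e-6)


class TestBirthDeathLik:
    def test_reduces_to_purebirth_at_zero_extinction(self):
        assert loglik_bd([2, 1], 0.2, 0.0) == pytest.approx(
            loglik_purebirth([1, 1], 0.2), abs=1e-12)

    def test_high_precision_value(self):
        # independent evaluation of the conditioned birth-death formula
        x = np.array([2.0, 1.0])
        r, a = 0.2, 0.5
        expected = (math.log(2) + math.log(r) + 3 * math.log(1 - a)
                    + r * 1.0
                    - 2 * sum(math.log(math.exp(r * xi) - a) for xi in x))
        assert loglik_bd(x, r, a) == pytest.approx(expected, abs=1e-12)
        assert loglik_bd(x, r, a) == pytest.approx(-2.126203, abs=2e-5)

    def test_parameter_recovery(self):
        rs = []
        for s in range(60):
            t = simulate_bd(200, 0.2, 0.1, seed=s)   # r = 0.1, a = 0.5
            rs.append(fit_bd(t.branching_times()).params["r1"])
        assert abs(np.median(rs) - 0.1) < 0.015

    def test_invalid_domain(self):
        with pytest.raises(ValueError):
            loglik_bd([2, 1], 0.2, 1.0)


class TestDensityDependent:
    def test_ddx_hand_value(self):
        # n=3, g=(1,1), r1=0.2, x=1: lam_2 = 0.1, lam_3 = 0.0667
        assert loglik_density_dependent([1, 1], "DDX", 0.2, x=1) == \
            pytest.approx(math.log(0.2) - 0.4, abs=1e-9)

    def test_ddx_zero_exponent_is_purebirth(self, yule_trees):
        for t in yule_trees:
            g = t.internode_intervals()
            assert loglik_density_dependent(g, "DDX", 0.33, x=0.0) == \
                pytest.approx(loglik_purebirth(g, 0.33), abs=1e-12)

    def test_ddl_limit_is_purebirth(self, yule_trees):
        for t in yule_trees:
            g = t.internode_intervals()
            assert abs(loglik_density_dependent(g, "DDL", 0.33, K=1e9)
                       - loglik_purebirth(g, 0.33)) < 1e-6

    def test_ddl_requires_k_above_n(self):
        with pytest.raises(ValueError):
            loglik_density_dependent([1, 1], "DDL", 0.2, K=3)

    def test_fit_at_optimum_beats_grid(self, yule_trees):
        g = yule_trees[0].internode_intervals()
        for variant, key in (("DDL", "K"), ("DDX", "x")):
            fit = fit_density_dependent(g, variant)
            for shape in ([50, 200, 1e4] if variant == "DDL"
                          else [0.0, 0.5, 2.0]):
                ll = loglik_density_dependent(g, variant, 1.0,
                                              **{key: shape})
                # profile the rate at this shape before comparing
                n = g.size + 1
                k = np.arange(2, n + 1)
                c = (1 - k / shape) if variant == "DDL" else k ** (-shape)
                r1 = (n - 2) / np.sum(k * c * g)
                ll = loglik_density_dependent(g, variant, r1, **{key: shape})
                assert fit.lnL >= ll - 1e-8


class TestMultirateLik:
    def test_equal_rates_reduce_to_purebirth(self, yule_trees):
        for t in yule_trees:
            g = t.internode_intervals()
            x = t.branching_times()
            assert loglik_yule_multirate(g, [0.4, 0.4], [x[4]]) == \
                pytest.approx(loglik_purebirth(g, 0.4), abs=1e-10)
            assert loglik_yule_multirate(g, [0.4] * 3, [x[3], x[8]]) == \
                pytest.approx(loglik_purebirth(g, 0.4), abs=1e-10)

    def test_fitted_shift_at_observed_branching_time(self, yule_trees):
        for t in yule_trees[:4]:
            fit = fit_yule_multirate(t.internode_intervals(), 2)
            assert fit.params["st"] in t.branching_times()

    def test_shift_age_recovery_tenfold(self):
        # 10x rate drop: the fitted shift lands within one branching event
        # of the interval containing the true shift age
        hits = 0
        B = 100
        for s in range(B):
            t = simulate_multirate_yule(100, [5.0, 0.5], [0.5], seed=s)
            true_age = t.shift_ages[0]
            x = t.branching_times()
            st = fit_yule_multirate(t.internode_intervals(), 2).params["st"]
            j = int(np.argmin(np.abs(x - st)))
            k = int(np.sum(x > true_age))     # x[k-1] > true_age >= x[k]
            hits += min(abs(j - (k - 1)), abs(j - k)) <= 1
        assert hits / B >= 0.8

    def test_too_few_branching_times(self):
        with pytest.raises(ValueError):
            fit_yule_multirate([1.0, 1.0], 3)


class TestSuiteAndAIC:
    def test_aic_arithmetic(self):
        fit = DiversificationFit("pureBirth", {"r1": 0.087}, 211.705, 1)
        assert fit.aic == pytest.approx(-421.410, abs=1e-9)
        fit3 = DiversificationFit("yule3rate", {}, 232.127, 5)
        assert fit3.aic == pytest.approx(-454.254, abs=1e-9)

    def test_best_model_has_zero_delta(self, yule_trees):
        res = BDLModel(yule_trees[0]).fit()
        assert res.delta_aic[res.best_model] == 0.0
        assert min(res.delta_aic.values()) == 0.0
        assert len(res.fits) == 6

    def test_aic_ordering_invariant_to_lnl_constant(self, yule_trees):
        res = BDLModel(yule_trees[1]).fit()
        shifted = {m: DiversificationFit(m, f.params, f.lnL + 17.3, f.k)
                   for m, f in res.fits.items()}
        from macrodiv.bdl import BDLResults
        res2 = BDLResults(shifted)
        assert res2.best_model == res.best_model

    def test_table_shape(self, yule_trees):
        table = BDLModel(yule_trees[2]).fit().table()
        assert list(table.index) == ["Parameters", "Ln(L)", "AIC", "dAIC"]
        assert table.shape[1] == 6

    def test_specificity_against_smooth_rv_models(self):
        # on pure-birth data the rate-constant model should stay within 2
        # AIC units of the smooth rate-variable alternatives
        ok = 0
        B = 40
        for s in range(B):
            t = simulate_yule(150, 1.0, seed=4000 + s)
            res = BDLModel(t, models=("pureBirth", "bd", "DDL", "DDX")
                           ).fit()
            d = (res.fits["pureBirth"].aic
                 - min(f.aic for f in res.fits.values()))
            ok += d < 2.0
        assert ok / B >= 0.9


class TestDeltaAICSignificance:
    def test_zero_observed_delta_is_insignificant(self):
        # at this size the rate-variable side essentially always improves
        # the AIC under the null, so an observed improvement of zero is as
        # unremarkable as possible
        p = delta_aic_significance(0.0, 100, 100, B=100, seed=1)
        assert p > 0.9

    def test_null_invariant_to_simulation_rate(self):
        # Yule-family delta-AIC is scale-free, so the simulated null does
        # not depend on the (arbitrary) rate: two independent nulls agree
        from scipy.stats import kstest
        _, null1 = delta_aic_significance(1.0, 35, 35, B=150, seed=2,
                                          return_null=True)
        _, null2 = delta_aic_significance(1.0, 35, 35, B=150, seed=3,
                                          return_null=True)
        assert kstest(null1, null2).pvalue > 0.01

    def test_scaled_trees_give_identical_delta(self):
        t = simulate_yule(40, 1.0, seed=9)
        d1 = BDLModel(t).fit().delta_aic_rc_rv
        d2 = BDLModel(t.scale(13.7)).fit().delta_aic_rc_rv
        assert d1 == pytest.approx(d2, abs=1e-6)
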