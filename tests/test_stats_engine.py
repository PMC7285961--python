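"""Regression fits, AIC selection, CMP model and Fisher exact test.

statsmodels and scipy serve only as independent oracles here; everything
under test is the package's own implementation.
"""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from normaudit import stats_engine as se


def sim_frame(rng, n=225, beta_year=0.0, sigma=10.0, journal_effects=None):
    years = rng.choice(np.arange(2013, 2018), size=n)
    journals = rng.choice([f"J{i}" for i in range(1, 7)], size=n)
    je = journal_effects or {}
    y = (
        10.0
        + beta_year * (years - 2015)
        + np.array([je.get(j, 0.0) for j in journals])
        + rng.normal(0, sigma, n)
    )
    return pd.DataFrame({"score": y, "year": years, "journal": journals})


class TestOLS:
    def test_exact_linear_fit_recovers_coefficients(self):
        years = np.arange(2013, 2018).repeat(4)
        df = pd.DataFrame({"score": 3.0 + 2.0 * years, "year": years})
        spec = se.ModelSpec("score", year_form=1, include_journal=False)
        fit = se.ols_fit(spec, df, term_tests=False)
        # year is centred, so the slope carries the signal exactly
        assert fit.param("year") == pytest.approx(2.0, abs=1e-9)
        X, _, _ = spec.build_design(df)
        assert np.allclose(X @ fit.params, df["score"], atol=1e-9)
        assert np.isfinite(fit.aic)  # guarded even at zero residual variance

    def test_two_points_interpolated_exactly(self):
        df = pd.DataFrame({"score": [1.0, 5.0], "year": [2013, 2017], "journal": ["J1", "J1"]})
        spec = se.ModelSpec("score", year_form=1, include_journal=False)
        fit = se.ols_fit(spec, df, term_tests=False)
        X, _, _ = spec.build_design(df)
        assert np.allclose(X @ fit.params, df["score"], atol=1e-10)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(11)
        df = sim_frame(rng, beta_year=2.0, journal_effects={"J2": 5.0})
        spec = se.ModelSpec("score", year_form=2)
        fit = se.ols_fit(spec, df, term_tests=False)
        X, _, _ = spec.build_design(df)
        ref = sm.OLS(df["score"].to_numpy(), X).fit()
        assert np.allclose(fit.params, ref.params, atol=1e-8)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        # this AIC counts the error variance as a parameter (R convention):
        # statsmodels OLS does not, hence the +2
        assert fit.aic == pytest.approx(ref.aic + 2.0, abs=1e-6)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(3)
        df = sim_frame(rng, n=60)
        df["year"] = 2015  # constant year -> centred poly column of zeros
        with pytest.raises((se.RankDeficientError, ValueError)):
            se.ols_fit(se.ModelSpec("score", year_form=1), df, term_tests=False)

    def test_n_must_exceed_parameters(self):
        df = pd.DataFrame(
            {"score": [1.0, 2.0], "year": [2013, 2014], "journal": ["J1", "J2"]}
        )
        with pytest.raises(ValueError):
            se.ols_fit(se.ModelSpec("score", year_form=1), df)


class TestLogistic:
    def test_matches_statsmodels(self):
        rng = np.random.default_rng(7)
        df = sim_frame(rng, n=400)
        eta = -0.5 + 0.3 * (df["year"] - 2015)
        df["valid"] = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(int)
        spec = se.ModelSpec("valid", year_form=1)
        fit = se.logistic_fit(spec, df, term_tests=False)
        X, _, _ = spec.build_design(df)
        ref = sm.Logit(df["valid"].to_numpy(), X).fit(disp=0)
        assert np.allclose(fit.params, ref.params, atol=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)
        assert fit.aic == pytest.approx(ref.aic, abs=1e-5)
        assert np.allclose(fit.bse, ref.bse, rtol=1e-4)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(123)
        n = 5000
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1.0 + 0.8 * x)))
        df = pd.DataFrame(
            {"valid": (rng.random(n) < p).astype(int), "year": 2013 + (x - x.min()).astype(int) % 5, "journal": "J1"}
        )
        # fit on the raw covariate via a hand-built design
        X = np.column_stack([np.ones(n), x])
        beta, ll, cov = se._logistic_core(X, df["valid"].to_numpy(float))
        se_b = np.sqrt(np.diag(cov))
        assert abs(beta[0] - (-1.0)) < 3 * se_b[0]
        assert abs(beta[1] - 0.8) < 3 * se_b[1]

    def test_degenerate_response_rejected(self):
        df = pd.DataFrame({"valid": [0, 0, 0, 0], "year": [2013, 2014, 2015, 2016], "journal": "J1"})
        with pytest.raises(ValueError, match="degenerate"):
            se.logistic_fit(se.ModelSpec("valid", year_form=1, include_journal=False), df)

    def test_complete_separation_flagged(self):
        years = np.arange(2013, 2018).repeat(10)
        df = pd.DataFrame(
            {"valid": (years >= 2015).astype(int), "year": years, "journal": "J1"}
        )
        with pytest.raises(se.ConvergenceError):
            se.logistic_fit(
                se.ModelSpec("valid", year_form=1, include_journal=False), df
            )


class TestModelSelection:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(5)
        df = sim_frame(rng)
        spec = se.ModelSpec("score", year_form=1)
        sel = se.aic_model_select([spec], df)
        assert sel.best.spec == spec

    def test_tie_breaks_to_first_listed(self):
        rng = np.random.default_rng(5)
        df = sim_frame(rng)
        a = se.ModelSpec("score", year_form=1)
        b = se.ModelSpec("score", year_form=1)
        sel = se.aic_model_select([a, b], df)
        assert sel.best is sel.fits[0]

    def test_failed_candidates_excluded_with_reason(self):
        rng = np.random.default_rng(5)
        df = sim_frame(rng, n=20)
        ok = se.ModelSpec("score", year_form=1)
        doomed = se.ModelSpec("score", year_form="factor", interaction=True)  # p > n
        sel = se.aic_model_select([doomed, ok], df)
        assert sel.best.spec == ok
        statuses = sel.ranking.set_index("model")["status"]
        assert statuses.str.startswith("failed").any()

    def test_deviance_monotone_in_nesting(self):
        """Adding predictors never lowers the maximized log-likelihood."""
        rng = np.random.default_rng(17)
        df = sim_frame(rng, beta_year=1.0)
        lls = [
            se.ols_fit(se.ModelSpec("score", year_form=d), df, term_tests=False).loglik
            for d in (1, 2, 3, 4)
        ]
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))


class TestLRTest:
    def _fits(self, rng, beta_year=0.0):
        df = sim_frame(rng, beta_year=beta_year)
        nested = se.ols_fit(se.ModelSpec("score", year_form=None), df, term_tests=False)
        full = se.ols_fit(se.ModelSpec("score", year_form=1), df, term_tests=False)
        return nested, full

    def test_identical_models_give_p_one(self):
        rng = np.random.default_rng(2)
        nested, _ = self._fits(rng)
        res = se.lr_test(nested, nested)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(2)
        df = sim_frame(rng)
        poly = se.ols_fit(se.ModelSpec("score", year_form=2), df, term_tests=False)
        factor = se.ols_fit(se.ModelSpec("score", year_form="factor"), df, term_tests=False)
        with pytest.raises(ValueError, match="nest"):
            se.lr_test(poly, factor)

    def test_extra_useless_parameter_is_chi2_1(self):
        """Null LR statistics across seeds behave like one-df chi-square."""
        stats_ = []
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            nested, full = self._fits(rng)
            stats_.append(se.lr_test(nested, full).statistic)
        ks = scipy.stats.kstest(stats_, scipy.stats.chi2(df=1).cdf)
        assert ks.pvalue > 0.01


class TestCmpDistribution:
    def test_poisson_reduction_at_zero(self):
        assert se.cmp_log_pmf(0, 2.0, 1.0) == pytest.approx(-2.0, abs=1e-12)

    def test_brute_force_series_oracle(self):
        # independent brute-force series for Z(2, 2); terms past j=60 are
        # below 1e-140 and cannot move the double-precision sum
        z = sum(2.0**j / math.factorial(j) ** 2 for j in range(61))
        assert se.cmp_log_pmf(0, 2.0, 2.0) == pytest.approx(-math.log(z), abs=1e-12)

    @pytest.mark.parametrize("lam", [0.5, 2.0, 8.0])
    def test_matches_poisson_at_nu_one(self, lam):
        ys = np.arange(0, 30)
        ours = se.cmp_log_pmf(ys, lam, 1.0)
        ref = scipy.stats.poisson.logpmf(ys, lam)
        assert np.max(np.abs(ours - ref)) < 1e-12

    @pytest.mark.parametrize("lam", [0.5, 2.0, 8.0])
    @pytest.mark.parametrize("nu", [0.5, 1.0, 3.0])
    def test_pmf_normalizes(self, lam, nu):
        total = se.cmp_pmf_table(lam, nu).sum()
        assert abs(total - 1.0) < 1e-9

    def test_variance_shrinks_as_nu_grows_at_fixed_mean(self):
        """Underdispersion: at a fixed mean of 2, variance decreases in nu."""
        target = 2.0
        variances = []
        for nu in (0.5, 1.0, 2.0, 3.0):
            lo, hi = 1e-3, 1e3
            for _ in range(200):
                lam = math.sqrt(lo * hi)
                m, _ = se.cmp_mean_var(lam, nu)
                lo, hi = (lam, hi) if m < target else (lo, lam)
            m, v = se.cmp_mean_var(lam, nu)
            assert m == pytest.approx(target, abs=1e-3)
            variances.append(v)
        assert all(b < a for a, b in zip(variances, variances[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            se.cmp_log_pmf(-1, 2.0, 1.0)
        with pytest.raises(ValueError):
            se.cmp_log_pmf(1.5, 2.0, 1.0)
        with pytest.raises(ValueError):
            se.cmp_log_z(0.0, 1.0)


class TestCmpRegression:
    def _two_group(self, rng, n=800, lam0=2.0, ratio=1.5, nu=1.0):
        from normaudit.synthetic_data import cmp_sample

        y0 = cmp_sample(lam0, nu, n, rng=rng)
        y1 = cmp_sample(lam0 * ratio, nu, n, rng=rng)
        y = np.concatenate([y0, y1])
        g = np.concatenate([np.zeros(n), np.ones(n)])
        return y, g

    def test_poisson_data_matches_poisson_oracle(self):
        rng = np.random.default_rng(99)
        y, g = self._two_group(rng, nu=1.0)
        fit = se.cmp_regression_fit(y, g)
        assert fit.nu == pytest.approx(1.0, abs=0.15)
        X = np.column_stack([np.ones_like(g), g])
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        for i in range(2):
            assert abs(fit.beta[i] - ref.params[i]) < 2 * ref.bse[i]

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            se.cmp_regression_fit([1, 2, 3, 2], [1, 1, 1, 1])

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            se.cmp_regression_fit([2, 2, 2, 2], [0, 0, 1, 1])

    def test_loglik_not_below_poisson_special_case(self):
        rng = np.random.default_rng(4)
        y, g = self._two_group(rng, n=300, nu=2.0)
        free = se.cmp_regression_fit(y, g)
        pois = se.cmp_regression_fit(y, g, fix_nu=1.0)
        assert free.loglik >= pois.loglik - 1e-6


class TestDispersionCheck:
    def _replicates(self, nu, n=400, reps=15):
        verdicts = []
        for seed in range(reps):
            rng = np.random.default_rng(5000 + seed)
            from normaudit.synthetic_data import cmp_sample

            y0 = cmp_sample(2.0, nu, n, rng=rng)
            y1 = cmp_sample(3.0, nu, n, rng=rng)
            y = np.concatenate([y0, y1])
            g = np.concatenate([np.zeros(n), np.ones(n)])
            verdicts.append(se.dispersion_check(y, g).verdict)
        return verdicts

    def test_poisson_data_called_equidispersed(self):
        v = self._replicates(nu=1.0)
        assert v.count("equidispersed") >= 0.9 * len(v)

    def test_underdispersed_data_detected(self):
        v = self._replicates(nu=3.0)
        assert v.count("underdispersed") >= 0.9 * len(v)

    def test_binary_counts_underdispersed(self):
        y = np.tile([0, 1], 200)
        g = np.repeat([0, 1], 200)
        assert se.dispersion_check(y, g).verdict == "underdispersed"


class TestFisherExact:
    def test_most_probable_table_gives_one(self):
        assert se.fisher_exact_2x2([[2, 2], [2, 2]]).pvalue == 1.0

    def test_perfect_association_enumeration(self):
        # 6 possible tables; only the two extremes are as improbable
        assert se.fisher_exact_2x2([[5, 0], [0, 5]]).pvalue == pytest.approx(
            2 / 252, rel=1e-12
        )

    def test_fixture_rna18s_contrast(self):
        res = se.fisher_exact_2x2([[1, 66], [18, 140]])
        ref = scipy.stats.fisher_exact([[1, 66], [18, 140]])[1]
        assert res.pvalue == pytest.approx(ref, rel=1e-9)
        assert round(res.pvalue, 2) == 0.02

    @given(
        st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
    )
    @settings(max_examples=150, deadline=None)
    def test_transposition_and_double_swap_invariance(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = se.fisher_exact_2x2([[a, b], [c, d]]).pvalue
        assert se.fisher_exact_2x2([[a, c], [b, d]]).pvalue == pytest.approx(p, rel=1e-9)
        assert se.fisher_exact_2x2([[d, c], [b, a]]).pvalue == pytest.approx(p, rel=1e-9)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            se.fisher_exact_2x2([[-1, 2], [3, 4]])

    def test_sample_odds_ratio(self):
        res = se.fisher_exact_2x2([[4, 1], [2, 3]])
        assert res.odds_ratio == pytest.approx(6.0)
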