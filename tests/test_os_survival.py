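"""Survival analytics: KM hand checks, Cox vs brute-force oracle, AFT MLE
vs closed forms and an independent lifelines fit, family selection,
elimination and median prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import LogNormalAFTFitter

from tgios import (
    REFERENCE_OS_MODEL,
    backward_eliminate,
    cox_fit,
    cox_hr_binary,
    fit_aft,
    km_estimate,
    predict_median,
    screen_covariates,
    select_family,
    weeks_to_months,
)
from tgios.os_survival import km_curve_fast, km_median_fast


def surv_df(times, events, **covs):
    df = pd.DataFrame({"ID": [f"p{i}" for i in range(len(times))],
                       "TIME_WK": times, "EVENT": events})
    for k, v in covs.items():
        df[k] = v
    return df


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        # event 2, censored 3, event 4, censored 5:
        # S(2) = 3/4, S(4) = 3/4 * 1/2 = 0.375
        km = km_estimate([2, 3, 4, 5], [1, 0, 1, 0])
        assert km.evaluate(2.0) == pytest.approx(0.75)
        assert km.evaluate(4.5) == pytest.approx(0.375)

    def test_no_censoring_matches_empirical_cdf(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10.0, 40)
        km = km_estimate(t, np.ones(40, bool))
        grid = np.linspace(0.1, 30, 23)
        ecdf = np.array([(t > g).mean() for g in grid])
        np.testing.assert_allclose(km.evaluate(grid), ecdf, atol=1e-12)

    def test_all_events_at_one_time_drops_to_zero(self):
        km = km_estimate([5, 5, 5], [1, 1, 1])
        assert km.evaluate(5.0) == pytest.approx(0.0)
        assert km.median == pytest.approx(5.0)

    def test_all_censored_flagged(self):
        with pytest.warns(UserWarning):
            km = km_estimate([3, 4], [0, 0])
        assert np.isnan(km.median)

    def test_fast_path_agrees_with_lifelines(self):
        rng = np.random.default_rng(2)
        t = np.round(rng.exponential(10.0, 120), 0) + 1  # heavy ties
        e = rng.random(120) < 0.7
        km = km_estimate(t, e)
        et, s = km_curve_fast(t, e)
        grid = np.linspace(0.5, 40, 50)
        idx = np.searchsorted(et, grid, side="right")
        fast = np.concatenate([[1.0], s])[idx]
        np.testing.assert_allclose(km.evaluate(grid), fast, atol=1e-10)
        assert km_median_fast(t, e) == pytest.approx(km.median)


class TestCox:
    def test_identical_groups_null(self):
        t = [3, 5, 7, 9, 3, 5, 7, 9]
        e = [1] * 8
        df = surv_df(t, e, X=[0, 0, 0, 0, 1, 1, 1, 1])
        res = cox_fit(df, "X")
        assert res.hr == pytest.approx(1.0, abs=1e-6)
        assert res.score == pytest.approx(0.0, abs=1e-6)

    def test_partial_likelihood_matches_grid_oracle(self):
        # brute-force Breslow/Efron partial likelihood on 4 records, no ties
        times = np.array([2.0, 4.0, 6.0, 9.0])
        events = np.array([1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])

        def pll(beta):
            order = np.argsort(times)
            ll = 0.0
            for i in order:
                if events[i]:
                    risk = times >= times[i]
                    ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        beta_axis = np.linspace(-5, 5, 2001)
        pll_vals = np.array([pll(b) for b in beta_axis])
        beta_grid = beta_axis[np.argmax(pll_vals)]
        df = surv_df(times, events, X=x)
        res = cox_fit(df, "X", unit=1.0)
        assert np.log(res.hr) == pytest.approx(beta_grid, abs=1e-2)

    def test_fast_binary_cox_agrees_with_lifelines(self):
        rng = np.random.default_rng(3)
        n = 300
        g = (rng.random(n) < 0.5).astype(int)
        t = np.round(rng.lognormal(4.0 - 0.3 * g, 0.7, n), 0) + 1
        c = rng.uniform(50, 140, n)
        e = t <= c
        obs = np.where(e, t, c)
        df = surv_df(obs, e.astype(int), ARMX=g)
        res = cox_fit(df, "ARMX", unit=1.0)
        hr, lr, p = cox_hr_binary(obs, e, g)
        assert hr == pytest.approx(res.hr, rel=1e-4)
        assert lr == pytest.approx(res.score, rel=1e-4)
        assert p == pytest.approx(res.p, rel=1e-3, abs=1e-12)

    def test_ttg_protective_sign_on_simulated_data(self, os_cohort):
        res = cox_fit(os_cohort, "TTG_WK")
        assert res.sign == "-"
        # reported per 8 weeks of TTG: protective HR well below 1
        assert res.hr < 0.95

    def test_screening_ranks_ttg_first(self, os_cohort):
        rng = np.random.default_rng(0)
        df = os_cohort.copy()
        df["NOISE1"] = rng.standard_normal(len(df))
        df["NOISE2"] = rng.standard_normal(len(df))
        ranked = screen_covariates(df, ["TTG_WK", "NOISE1", "NOISE2"])
        assert ranked[0].covariate == "TTG_WK"
        assert ranked[0].p < 1e-6

    def test_empty_candidate_list(self, os_cohort):
        assert screen_covariates(os_cohort, []) == []


class TestAFT:
    def test_intercept_only_lognormal_no_censoring(self):
        rng = np.random.default_rng(4)
        t = rng.lognormal(4.0, 0.5, 500)
        df = surv_df(t, np.ones(500, int))
        m = fit_aft(df, [], family="lognormal")
        logt = np.log(t)
        assert m.coefficients["Intercept"] == pytest.approx(logt.mean(),
                                                            abs=1e-4)
        assert m.scale == pytest.approx(logt.std(), rel=1e-3)

    def test_matches_lifelines_lognormal_aft(self, os_cohort):
        covs = ["TTG_WK", "BTS_CM", "AGE_GE55", "ASIAN", "ECOG_GT0", "FEMALE"]
        m = fit_aft(os_cohort, covs, family="lognormal")
        ll = LogNormalAFTFitter()
        ll.fit(os_cohort[["TIME_WK", "EVENT"] + covs], duration_col="TIME_WK",
               event_col="EVENT")
        for c in covs:
            assert m.coefficients[c] == pytest.approx(
                ll.params_[("mu_", c)], abs=1e-4)
        assert m.coefficients["Intercept"] == pytest.approx(
            ll.params_[("mu_", "Intercept")], abs=1e-4)
        assert m.log_scale == pytest.approx(
            ll.params_[("sigma_", "Intercept")], abs=1e-3)
        # lifelines reports loglik of the same density; AIC must agree
        assert m.aic == pytest.approx(ll.AIC_, rel=1e-6)

    def test_standard_errors_close_to_lifelines(self, os_cohort):
        covs = ["TTG_WK", "BTS_CM"]
        m = fit_aft(os_cohort, covs, family="lognormal")
        ll = LogNormalAFTFitter()
        ll.fit(os_cohort[["TIME_WK", "EVENT"] + covs], duration_col="TIME_WK",
               event_col="EVENT")
        assert m.standard_errors["TTG_WK"] == pytest.approx(
            ll.standard_errors_[("mu_", "TTG_WK")], rel=0.02)

    def test_rank_deficiency_names_columns(self, os_cohort):
        df = os_cohort.copy()
        df["DUP"] = df["TTG_WK"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_aft(df, ["TTG_WK", "DUP"])

    def test_no_events_rejected(self):
        df = surv_df([10.0, 12.0], [0, 0])
        with pytest.raises(ValueError, match="no events"):
            fit_aft(df, [])

    def test_exponential_nested_in_weibull(self, os_cohort):
        fits = {m.family: m for m in select_family(
            os_cohort, ["TTG_WK"], families=("weibull", "exponential"))}
        assert fits["weibull"].aic <= fits["exponential"].aic + 2.0 + 1e-6

    def test_lognormal_wins_on_lognormal_data(self, os_cohort):
        ranked = select_family(os_cohort,
                               ["TTG_WK", "BTS_CM", "AGE_GE55", "FEMALE"])
        assert ranked[0].family == "lognormal"


class TestEliminationAndPrediction:
    def test_strong_covariates_identity(self, os_cohort):
        covs = ["TTG_WK", "BTS_CM", "AGE_GE55"]
        final, trace = backward_eliminate(os_cohort, covs)
        assert set(final.covariate_names) == set(covs)
        assert trace == []

    def test_noise_covariate_eliminated(self, os_cohort):
        rng = np.random.default_rng(9)
        df = os_cohort.copy()
        df["NOISE"] = rng.standard_normal(len(df))
        final, trace = backward_eliminate(
            df, ["TTG_WK", "BTS_CM", "AGE_GE55", "NOISE"])
        assert "NOISE" not in final.covariate_names
        assert "TTG_WK" in final.covariate_names

    def test_reference_median_at_baseline(self):
        covs = dict(TTG_WK=0, BTS_CM=0, AGE_GE55=0, ASIAN=0, ECOG_GT0=0,
                    FEMALE=0)
        med = predict_median(REFERENCE_OS_MODEL, covs)
        assert med == pytest.approx(float(np.exp(4.3776)), rel=1e-9)

    def test_ttg_multiplicativity(self):
        base = dict(TTG_WK=5.0, BTS_CM=6.0, AGE_GE55=1, ASIAN=0, ECOG_GT0=1,
                    FEMALE=0)
        shifted = dict(base, TTG_WK=13.0)
        ratio = (predict_median(REFERENCE_OS_MODEL, shifted)
                 / predict_median(REFERENCE_OS_MODEL, base))
        assert ratio == pytest.approx(float(np.exp(8 * 0.0139)), rel=1e-9)

    def test_weeks_to_months(self):
        assert weeks_to_months(30.4375 / 7.0) == pytest.approx(1.0)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(ttg=st.floats(-20, 60), delta=st.floats(0.5, 20))
def test_aft_median_scales_exponentially_in_any_shift(ttg, delta):
    base = dict(TTG_WK=ttg, BTS_CM=6.0, AGE_GE55=0, ASIAN=0, ECOG_GT0=0,
                FEMALE=1)
    shifted = dict(base, TTG_WK=ttg + delta)
    ratio = (predict_median(REFERENCE_OS_MODEL, shifted)
             / predict_median(REFERENCE_OS_MODEL, base))
    assert ratio == pytest.approx(float(np.exp(delta * 0.0139)), rel=1e-9)
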