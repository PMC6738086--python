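"""The spline-on-log-cumulative-hazard fitting engine."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from prosash import flexpar
from prosash.flexpar import FitError, FlexParSpec
from prosash.model_core import RestrictedCubicSplineLogTime


def _censored_weibull_frame(shape, scale, n, seed, admin=30.0):
    rng = np.random.default_rng(seed)
    t = scale * rng.weibull(shape, n)
    obs = np.minimum(t, admin)
    return pd.DataFrame({"time": np.maximum(obs, 1e-9),
                         "event": (t <= admin).astype(int)})


def weibull_loglik(shape, scale, times, events):
    """Closed-form right-censored Weibull log likelihood (the oracle)."""
    t = np.asarray(times, float)
    d = np.asarray(events, float)
    z = (t / scale) ** shape
    return float(np.sum(d * (math.log(shape) - math.log(scale)
                             + (shape - 1) * (np.log(t) - math.log(scale)))
                        - z))


class TestPlaceKnots:
    def test_published_knot_convention(self):
        # two extreme event times and an odd number with a central median
        t = np.exp([-1.017, 0.2, 1.833, 2.9, 3.443])
        sp = flexpar.place_knots(t, np.ones(5, int), df=2)
        assert sp.boundary_knots == pytest.approx((-1.017, 3.443))
        assert sp.internal_knots[0] == pytest.approx(1.833)

    def test_df1_has_no_internal_knots(self):
        sp = flexpar.place_knots(np.array([1.0, 5.0, 20.0]),
                                 np.ones(3, int), df=1)
        assert sp.internal_knots == ()

    def test_df3_uses_terciles(self):
        logs = np.linspace(0.0, 3.0, 10)
        sp = flexpar.place_knots(np.exp(logs), np.ones(10, int), df=3)
        q = np.percentile(logs, [100 / 3, 200 / 3])
        assert np.allclose(sp.internal_knots, q)

    def test_too_few_events_is_an_error(self):
        with pytest.raises(FitError):
            flexpar.place_knots(np.array([1.0, 2.0, 3.0]),
                                np.array([1, 0, 0]), df=2)


class TestLogLikelihood:
    def test_all_censored_reduces_to_cumulative_hazard_sum(self):
        sp = RestrictedCubicSplineLogTime((-1.0, 3.0), (), (0.0, 1.0))
        df = pd.DataFrame({"time": [2.0, 5.0, 9.0], "event": [0, 0, 0]})
        gamma = (-2.0, 1.3)
        expected = -sum(math.exp(gamma[0] + gamma[1] * math.log(t))
                        for t in df["time"])
        got = flexpar.log_likelihood(gamma, [], df, sp)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_df1_equals_weibull_closed_form(self):
        df = pd.DataFrame({"time": [2.0, 7.0, 15.0], "event": [1, 0, 1]})
        sp = RestrictedCubicSplineLogTime((0.0, 3.0), (), (0.0, 1.0))
        gamma0, gamma1 = -3.1, 1.4
        shape = gamma1
        scale = math.exp(-gamma0 / gamma1)
        got = flexpar.log_likelihood((gamma0, gamma1), [], df, sp)
        assert got == pytest.approx(
            weibull_loglik(shape, scale, df["time"], df["event"]), rel=1e-12)

    def test_hazard_violation_returns_neg_inf(self):
        sp = RestrictedCubicSplineLogTime((-1.0, 3.0), (), (0.0, 1.0))
        df = pd.DataFrame({"time": [2.0, 5.0], "event": [1, 1]})
        assert flexpar.log_likelihood((0.0, -1.0), [], df, sp) == -np.inf

    def test_perturbing_beta_at_mle_decreases_loglik(self):
        df = _censored_weibull_frame(1.2, 10.0, 300, seed=4)
        rng = np.random.default_rng(0)
        df["x"] = rng.normal(size=len(df))
        fit = flexpar.fit(df, FlexParSpec(df=1, covariates=["x"]))
        sp = fit.spline
        g = list(fit.spline.gamma)
        b = fit.beta["x"]
        base = flexpar.log_likelihood(g, [b], df, sp, covariates=["x"])
        assert base == pytest.approx(fit.loglik, rel=1e-9)
        for db in (-0.05, 0.05):
            assert flexpar.log_likelihood(g, [b + db], df, sp,
                                          covariates=["x"]) < base


class TestFit:
    def test_df1_matches_independent_weibull_mle(self):
        df = _censored_weibull_frame(1.5, 8.0, 400, seed=2)
        fit = flexpar.fit(df, FlexParSpec(df=1))

        def nll(p):
            return -weibull_loglik(math.exp(p[0]), math.exp(p[1]),
                                   df["time"], df["event"])

        res = optimize.minimize(nll, [0.0, 2.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 5000})
        shape_hat, scale_hat = math.exp(res.x[0]), math.exp(res.x[1])
        g0, g1 = fit.spline.gamma
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-6)
        assert g1 == pytest.approx(shape_hat, abs=1e-4)
        assert math.exp(-g0 / g1) == pytest.approx(scale_hat, rel=1e-4)

    def test_parameter_recovery_single_seed(self, published, cohort_factory):
        df = cohort_factory(n=2000, seed=1)
        frame = flexpar.prosash_design_frame(df)
        fit = flexpar.fit(frame, FlexParSpec(df=2,
                                             covariates=flexpar.PROSASH_TERMS))
        name_map = {"aetiology[HBV]": "hbv", "aetiology[other]": "other_aetiology"}
        for col, est in fit.beta.items():
            true = published.coefficients[name_map.get(col, col)]
            assert abs(est - true) < 3 * fit.se(col), col

    def test_null_model_tracks_kaplan_meier(self):
        from lifelines import KaplanMeierFitter
        df = _censored_weibull_frame(1.3, 9.0, 1000, seed=5)
        fit = flexpar.fit(df, FlexParSpec(df=2))
        km = KaplanMeierFitter().fit(df["time"], df["event"])
        qs = np.quantile(df.loc[df["event"] == 1, "time"],
                         np.linspace(0.1, 0.9, 9))
        for t in qs:
            s_fit = math.exp(-math.exp(float(fit.spline(math.log(t))[0])))
            s_km = float(km.survival_function_at_times(t).iloc[0])
            assert abs(s_fit - s_km) < 0.03

    def test_null_covariate_rarely_flagged(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            df = _censored_weibull_frame(1.2, 10.0, 300, seed=100 + seed)
            rng = np.random.default_rng(seed)
            df["x"] = rng.integers(0, 2, len(df)).astype(float)
            fit = flexpar.fit(df, FlexParSpec(df=1, covariates=["x"]))
            if abs(fit.beta["x"]) < 3 * fit.se("x"):
                hits += 1
        assert hits >= int(0.9 * reps)

    def test_zero_events_is_an_error(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(FitError):
            flexpar.fit(df, FlexParSpec(df=1))

    def test_covariance_is_symmetric_psd(self):
        df = _censored_weibull_frame(1.4, 9.0, 300, seed=9)
        rng = np.random.default_rng(1)
        df["x"] = rng.normal(size=len(df))
        fit = flexpar.fit(df, FlexParSpec(df=2, covariates=["x"]))
        c = fit.covariance
        assert np.allclose(c, c.T)
        assert np.all(np.linalg.eigvalsh(c) > -1e-10)

    def test_time_unit_invariance(self):
        # months -> years shifts gamma but leaves beta, HRs and loglik
        # differences untouched
        df = _censored_weibull_frame(1.3, 9.0, 400, seed=11)
        rng = np.random.default_rng(3)
        df["x"] = rng.normal(size=len(df))
        df["z"] = rng.integers(0, 2, len(df)).astype(float)
        years = df.copy()
        years["time"] = df["time"] / 12.0
        spec_full = FlexParSpec(df=2, covariates=["x", "z"])
        spec_null = FlexParSpec(df=2)
        fm, fy = flexpar.fit(df, spec_full), flexpar.fit(years, spec_full)
        nm, ny = flexpar.fit(df, spec_null), flexpar.fit(years, spec_null)
        for k in ("x", "z"):
            assert fm.beta[k] == pytest.approx(fy.beta[k], abs=1e-6)
        d_m = fm.loglik - nm.loglik
        d_y = fy.loglik - ny.loglik
        assert d_m == pytest.approx(d_y, abs=1e-6)
        hr_m = flexpar.hazard_ratios(fm)["hr"]
        hr_y = flexpar.hazard_ratios(fy)["hr"]
        assert np.allclose(hr_m, hr_y, atol=1e-6)


class TestModelBuilding:
    def test_lr_test_identical_models_p_one(self):
        df = _censored_weibull_frame(1.2, 10.0, 200, seed=1)
        f = flexpar.fit(df, FlexParSpec(df=1))
        assert flexpar.lr_test(f, f) == 1.0

    def test_lr_test_chi2_quantile(self):
        # 2*delta-loglik = 3.841 on 1 df sits exactly at p = 0.05
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=1e-4)

    def test_lr_test_rejects_nonnested(self):
        a = _censored_weibull_frame(1.2, 10.0, 100, seed=1)
        b = _censored_weibull_frame(1.2, 10.0, 150, seed=2)
        fa = flexpar.fit(a, FlexParSpec(df=1))
        fb = flexpar.fit(b, FlexParSpec(df=2))
        with pytest.raises(ValueError):
            flexpar.lr_test(fb, fa)

    def test_lr_null_p_uniform(self):
        # junk covariate on null data: p-values should look uniform
        ps = []
        for seed in range(20):
            df = _censored_weibull_frame(1.2, 10.0, 200, seed=200 + seed)
            rng = np.random.default_rng(seed)
            df["junk"] = rng.normal(size=len(df))
            full = flexpar.fit(df, FlexParSpec(df=1, covariates=["junk"]))
            null = flexpar.fit(df, FlexParSpec(df=1))
            ps.append(flexpar.lr_test(null, full))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_select_df_single_candidate(self):
        df = _censored_weibull_frame(1.2, 10.0, 100, seed=3)
        assert flexpar.select_df(df, [4]) == 4

    def test_select_df_weibull_data_prefers_df1(self):
        picks = [flexpar.select_df(_censored_weibull_frame(1.3, 10.0, 400,
                                                           seed=s), [1, 2, 3])
                 for s in range(5)]
        assert sum(p == 1 for p in picks) >= 3

    def test_select_df_spline_data_prefers_df2(self, cohort_factory):
        picks = []
        for s in range(5):
            df = cohort_factory(n=500, seed=s)
            picks.append(flexpar.select_df(df[["time", "event"]], [1, 2, 3]))
        assert sum(p == 2 for p in picks) >= 3

    def test_backward_select_keeps_active_drops_null(self):
        keep_active = drop_null = 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(300 + seed)
            n = 600
            active = rng.integers(0, 2, n).astype(float)
            null = rng.normal(size=n)
            t = 10.0 * rng.weibull(1.2, n) * np.exp(-0.6 * active / 1.2)
            obs = np.minimum(t, 30.0)
            df = pd.DataFrame({"time": np.maximum(obs, 1e-9),
                               "event": (t <= 30.0).astype(int),
                               "active": active, "null": null})
            sel = flexpar.backward_select(df, ["active", "null"], alpha=0.05,
                                          df=1)
            keep_active += "active" in sel.spec.covariates
            drop_null += "null" not in sel.spec.covariates
        assert keep_active >= int(0.9 * reps)
        assert drop_null >= int(0.9 * reps)

    def test_backward_select_alpha_one_keeps_everything(self):
        df = _censored_weibull_frame(1.2, 10.0, 200, seed=6)
        rng = np.random.default_rng(0)
        df["a"] = rng.normal(size=len(df))
        df["b"] = rng.normal(size=len(df))
        sel = flexpar.backward_select(df, ["a", "b"], alpha=1.01, df=1)
        assert list(sel.spec.covariates) == ["a", "b"]
        assert sel.removal_order == []

    def test_backward_select_no_covariates_gives_null_model(self):
        df = _censored_weibull_frame(1.2, 10.0, 200, seed=6)
        sel = flexpar.backward_select(df, [], alpha=0.05, df=1)
        assert sel.spec.covariates == []

    def test_backward_select_removes_factor_blocks_whole(self):
        rng = np.random.default_rng(42)
        df = _censored_weibull_frame(1.2, 10.0, 400, seed=7)
        df["f"] = pd.Categorical(rng.choice(["a", "b", "c"], len(df)),
                                 categories=["a", "b", "c"])
        sel = flexpar.backward_select(df, ["f"], alpha=0.05, df=1)
        # the junk factor must leave as one block, never a single level
        assert sel.spec.covariates == [] or sel.spec.covariates == ["f"]


class TestTimeDependence:
    def test_td_effect_detected_when_shapes_differ(self):
        sig = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            g = rng.integers(0, 2, 800)
            shape = np.where(g == 1, 2.5, 1.0)
            t = 10.0 * rng.weibull(1.0, 800) ** (1.0 / shape)
            obs = np.minimum(t, 30.0)
            df = pd.DataFrame({"time": np.maximum(obs, 1e-9),
                               "event": (t <= 30.0).astype(int),
                               "g": g.astype(float)})
            fit = flexpar.fit(df, FlexParSpec(df=2, covariates=["g"]))
            sig += flexpar.test_td_effect(fit, df, "g") < 0.05
        assert sig >= 4

    def test_td_effect_null_p_not_degenerate(self):
        ps = []
        for seed in range(10):
            df = _censored_weibull_frame(1.3, 10.0, 300, seed=500 + seed)
            rng = np.random.default_rng(seed)
            df["g"] = rng.integers(0, 2, len(df)).astype(float)
            fit = flexpar.fit(df, FlexParSpec(df=2, covariates=["g"]))
            ps.append(flexpar.test_td_effect(fit, df, "g"))
        # proportional data: no systematic significance
        assert sum(p < 0.05 for p in ps) <= 3

    def test_td_effect_unknown_covariate_errors(self):
        df = _censored_weibull_frame(1.3, 10.0, 200, seed=1)
        fit = flexpar.fit(df, FlexParSpec(df=1))
        with pytest.raises(ValueError):
            flexpar.test_td_effect(fit, df, "ghost")


class TestResiduals:
    def test_martingale_residuals_sum_to_zero_for_null_model(self):
        df = _censored_weibull_frame(1.3, 9.0, 500, seed=8)
        fit = flexpar.fit(df, FlexParSpec(df=2))
        r = flexpar.martingale_residuals(fit, df)
        assert abs(r.sum()) < 1e-6 * len(df)

    def test_residual_signs_match_definition(self):
        df = _censored_weibull_frame(1.3, 9.0, 300, seed=21)
        fit = flexpar.fit(df, FlexParSpec(df=1))
        r = flexpar.martingale_residuals(fit, df)
        d = df["event"].to_numpy()
        H = fit.cumulative_hazard(df)
        assert np.allclose(r, d - H)
        # censored subjects can only accrue negative residuals
        assert np.all(r[d == 0] <= 0)
        early_censored = (d == 0) & (df["time"].to_numpy() < 0.5)
        if early_censored.any():
            assert np.all(r[early_censored] > -0.2)

    def test_correct_specification_shows_no_trend(self):
        rng = np.random.default_rng(12)
        n = 1000
        x = rng.normal(size=n)
        t = 10.0 * rng.weibull(1.2, n) * np.exp(-0.5 * x / 1.2)
        obs = np.minimum(t, 40.0)
        df = pd.DataFrame({"time": np.maximum(obs, 1e-9),
                           "event": (t <= 40.0).astype(int), "x": x})
        fit = flexpar.fit(df, FlexParSpec(df=2, covariates=["x"]))
        r = flexpar.martingale_residuals(fit, df)
        _, flag = flexpar.functional_form_check(r, x)
        assert not flag

    def test_wrong_functional_form_is_flagged(self):
        flags = 0
        for seed in range(3):
            rng = np.random.default_rng(700 + seed)
            n = 2000
            x = np.exp(rng.normal(0.0, 1.0, n))          # skewed covariate
            t = 8.0 * rng.weibull(1.2, n) * np.exp(-np.log(x) / 1.2)
            obs = np.minimum(t, 60.0)
            df = pd.DataFrame({"time": np.maximum(obs, 1e-9),
                               "event": (t <= 60.0).astype(int), "x": x})
            # true effect is log-linear; model it linearly
            fit = flexpar.fit(df, FlexParSpec(df=2, covariates=["x"]))
            r = flexpar.martingale_residuals(fit, df)
            _, flag = flexpar.functional_form_check(r, np.log(x))
            flags += flag
        assert flags >= 2

    def test_functional_form_check_degenerate_inputs(self):
        with pytest.raises(ValueError):
            flexpar.functional_form_check([0.1, -0.1], [1.0, 2.0])
        with pytest.raises(ValueError):
            flexpar.functional_form_check([0.1, -0.1, 0.0], [1.0, 1.0, 1.0])


class TestHazardRatios:
    @pytest.mark.parametrize("beta, hr", [(0.327, 1.387), (0.455, 1.576)])
    def test_published_coefficients_exponentiate_to_table_values(self, beta, hr):
        assert math.exp(beta) == pytest.approx(hr, abs=1e-3)

    def test_zero_coefficient_symmetric_ci(self):
        df = _censored_weibull_frame(1.2, 10.0, 400, seed=13)
        rng = np.random.default_rng(5)
        df["x"] = rng.normal(size=len(df))
        fit = flexpar.fit(df, FlexParSpec(df=1, covariates=["x"]))
        tbl = flexpar.hazard_ratios(fit)
        row = tbl.loc["x"]
        # CI is symmetric on the log scale by construction
        assert math.log(row["hr_upper"]) - math.log(row["hr"]) == \
            pytest.approx(math.log(row["hr"]) - math.log(row["hr_lower"]),
                          abs=1e-10)
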