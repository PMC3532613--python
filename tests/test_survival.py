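"""Kaplan-Meier, log-rank, Cox PH (vs direct partial-likelihood oracle)."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from oncorule.survival import (
    backward_elimination,
    compare_hazard_models,
    cox_fit,
    km_curve,
    logrank_test,
    prepare_covariates,
    univariate_screen,
)


def surv_df(times, events, **covs):
    return pd.DataFrame({"time_months": times, "event": events, **covs})


def sim_exponential(rng, n, coefs, base_rate=0.03, horizon=36.0):
    """Exponential survival data with log-linear covariate effects."""
    covs = {name: (rng.random(n) < 0.5).astype(float) if kind == "binary"
            else rng.normal(size=n)
            for name, (kind, _) in coefs.items()}
    lp = sum(beta * covs[name] for name, (_, beta) in coefs.items())
    t = rng.exponential(1.0, n) / (base_rate * np.exp(lp))
    return surv_df(np.minimum(t, horizon), (t <= horizon).astype(int), **covs)


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curves = km_curve(surv_df([5, 10, 15], [0, 0, 0]))
        assert (curves["all"]["survival"] == 1.0).all()

    def test_single_event_closed_form(self):
        curves = km_curve(surv_df([1, 2, 3, 4, 5], [0, 0, 1, 0, 0]))
        s = curves["all"].set_index("time")["survival"]
        # event at t=3 with 3 patients still at risk -> S = 2/3
        assert s.loc[3.0] == pytest.approx(2 / 3)

    def test_interleaved_censoring_matches_hand_table(self):
        # times 1,2,2,3,4,5 with events 1,0,1,1,0,1:
        #   t=1: 6 at risk, 1 event          -> 5/6
        #   t=2: 5 at risk, 1 event (1 cens) -> 5/6 * 4/5 = 2/3
        #   t=3: 3 at risk, 1 event          -> 2/3 * 2/3 = 4/9
        #   t=5: 1 at risk, 1 event          -> 0
        curves = km_curve(surv_df([1, 2, 2, 3, 4, 5], [1, 0, 1, 1, 0, 1]))
        s = curves["all"].set_index("time")["survival"]
        assert s.loc[1.0] == pytest.approx(5 / 6)
        assert s.loc[2.0] == pytest.approx(2 / 3)
        assert s.loc[3.0] == pytest.approx(4 / 9)
        assert s.loc[5.0] == pytest.approx(0.0)

    def test_nonincreasing_and_starts_at_one(self, rng):
        df = surv_df(rng.exponential(20, 50), rng.random(50) < 0.7,
                     group=rng.random(50) < 0.5)
        for curve in km_curve(df, group_col="group").values():
            s = curve["survival"].to_numpy()
            assert s[0] <= 1.0 and (np.diff(s) <= 1e-12).all()

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = np.round(rng.exponential(10, 40), 1) + 0.1
        curves = km_curve(surv_df(times, np.ones(40, dtype=int)))
        c = curves["all"]
        for t, s in zip(c["time"], c["survival"]):
            assert s == pytest.approx(np.mean(times > t), abs=1e-12)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            km_curve(pd.DataFrame(columns=["time_months", "event"]))


def logrank_oracle(times, events, groups):
    """Direct O-E / V computation over shared event times."""
    times, events, groups = map(np.asarray, (times, events, groups))
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_patterns_give_null(self):
        base_t, base_e = [2, 5, 9, 14], [1, 0, 1, 1]
        df = surv_df(base_t * 2, base_e * 2, group=[0] * 4 + [1] * 4)
        chi2, p = logrank_test(df, "group")
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_oracle(self):
        times = [3, 5, 7, 9, 11, 14, 20, 26]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        groups = [0, 1, 0, 1, 0, 1, 0, 1]
        df = surv_df(times, events, group=groups)
        chi2, _ = logrank_test(df, "group")
        assert chi2 == pytest.approx(logrank_oracle(times, events, groups), abs=1e-10)

    def test_invariant_to_label_swap(self, rng):
        df = surv_df(rng.exponential(20, 60), rng.random(60) < 0.6,
                     group=(rng.random(60) < 0.5).astype(int))
        chi2a, pa = logrank_test(df, "group")
        df2 = df.assign(group=1 - df["group"])
        chi2b, pb = logrank_test(df2, "group")
        assert chi2a == pytest.approx(chi2b)
        assert pa == pytest.approx(pb)

    def test_equals_cox_score_test_without_ties(self, rng):
        times = rng.exponential(20, 40)
        times += np.arange(40) * 1e-6  # guarantee no ties
        events = (rng.random(40) < 0.7).astype(int)
        x = (rng.random(40) < 0.5).astype(float)
        df = surv_df(times, events, group=x)
        chi2, _ = logrank_test(df, "group")

        # Cox score test at beta = 0: U(0)^2 / I(0)
        order = np.argsort(times)
        t_s, e_s, x_s = times[order], events[order], x[order]
        U = Info = 0.0
        for i in range(40):
            if e_s[i] != 1:
                continue
            risk = x_s[i:]
            xbar = risk.mean()
            U += x_s[i] - xbar
            Info += ((risk - xbar) ** 2).mean()
        assert chi2 == pytest.approx(U**2 / Info, abs=1e-8)

    def test_one_group_empty_raises(self):
        with pytest.raises(ValueError):
            logrank_test(surv_df([1, 2], [1, 1], group=[0, 0]), "group")


def cox_partial_loglik(beta, times, events, x):
    """Written-out partial likelihood for one covariate, no ties."""
    order = np.argsort(times)
    t_s, e_s, x_s = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(t_s)):
        if e_s[i] == 1:
            ll += beta * x_s[i] - np.log(np.sum(np.exp(beta * x_s[i:])))
    return ll


class TestCoxFit:
    def test_mirrored_groups_give_unit_hazard_ratio(self):
        # both groups see the same event/censoring pattern
        df = surv_df([2, 5, 9, 14, 2, 5, 9, 14], [1, 1, 0, 1] * 2,
                     group=[0.0] * 4 + [1.0] * 4)
        fit = cox_fit(df, ["group"])
        assert fit.hr("group") == pytest.approx(1.0, abs=1e-6)

    def test_matches_partial_likelihood_oracle(self, rng):
        times = rng.exponential(15, 30) + np.linspace(0, 1e-4, 30)  # no ties
        x = (rng.random(30) < 0.5).astype(float)
        events = (rng.random(30) < 0.8).astype(int)
        df = surv_df(times, events, group=x)
        fit = cox_fit(df, ["group"])
        oracle = minimize_scalar(
            lambda b: -cox_partial_loglik(b, times, events, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert float(fit.summary.loc["group", "coef"]) == pytest.approx(
            oracle.x, abs=1e-6
        )

    def test_rank_invariance_under_time_transform(self, rng):
        times = rng.exponential(15, 50) + np.linspace(0, 1e-4, 50)
        x = rng.normal(size=50)
        events = (rng.random(50) < 0.7).astype(int)
        f1 = cox_fit(surv_df(times, events, z=x), ["z"])
        f2 = cox_fit(surv_df(times**1.7, events, z=x), ["z"])
        assert float(f1.summary.loc["z", "coef"]) == pytest.approx(
            float(f2.summary.loc["z", "coef"]), abs=1e-6
        )

    def test_complete_case_accounting(self, rng):
        df = sim_exponential(rng, 200, {"x": ("binary", 0.7)})
        df.loc[df.index[:40], "x"] = np.nan
        fit = cox_fit(df, ["x"])
        assert fit.n_used == 160
        assert fit.n_excluded == 40

    def test_constant_covariate_rejected(self):
        df = surv_df([1, 2, 3, 4], [1, 1, 0, 1], x=[1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["x"])

    def test_no_events_rejected(self):
        df = surv_df([1, 2, 3], [0, 0, 0], x=[0.0, 1.0, 0.5])
        with pytest.raises(ValueError, match="events"):
            cox_fit(df, ["x"])


class TestUnivariateScreen:
    def test_row_count_and_n_used(self, rng):
        df = sim_exponential(rng, 300, {"test": ("binary", 0.7),
                                        "z1": ("normal", 0.0),
                                        "z2": ("normal", 0.0)})
        df.loc[df.index[:60], "z1"] = np.nan
        table = univariate_screen(df, ["z1", "z2"], "test")
        assert len(table) == 2
        assert table.loc["z1", "n_used"] == 240
        assert table.loc["z2", "n_used"] == 300

    def test_adjusted_hrs_near_marginal_for_independent_covariates(self, rng):
        df = sim_exponential(rng, 1500, {"test": ("binary", np.log(2.0)),
                                         "z": ("normal", 0.0)})
        table = univariate_screen(df, ["z"], "test")
        assert table.loc["z", "variable_hr"] == pytest.approx(1.0, abs=0.15)
        assert table.loc["z", "test_adjusted_hr"] == pytest.approx(2.0, rel=0.15)

    def test_per_variable_failure_reported_not_raised(self, rng):
        df = sim_exponential(rng, 100, {"test": ("binary", 0.5)})
        df["broken"] = 1.0  # constant
        table = univariate_screen(df, ["broken"], "test")
        assert table.loc["broken", "error"] != ""


class TestBackwardElimination:
    def test_all_significant_model_unchanged(self, rng):
        df = sim_exponential(rng, 600, {"sig": ("binary", 0.9),
                                        "x1": ("binary", 0.9)})
        fit, trace = backward_elimination(df, ["sig", "x1"], forced="sig")
        assert trace.empty
        assert set(fit.summary.index) == {"sig", "x1"}

    def test_forced_variable_survives_high_p(self, rng):
        df = sim_exponential(rng, 400, {"sig": ("binary", 0.0),
                                        "x1": ("binary", 1.0)})
        fit, _ = backward_elimination(df, ["sig", "x1"], forced="sig")
        assert "sig" in fit.summary.index

    def test_noise_variable_eliminated_first(self):
        """A pure-noise covariate among strong predictors is the first
        variable dropped in >= 95% of 100 seeded simulations."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            df = sim_exponential(rng, 250, {"sig": ("binary", 0.6),
                                            "x1": ("binary", 0.9),
                                            "x2": ("normal", 0.8),
                                            "noise": ("normal", 0.0)})
            _, trace = backward_elimination(df, ["sig", "x1", "x2", "noise"],
                                            forced="sig")
            if trace.empty or trace.iloc[0]["dropped"] == "noise":
                hits += 1
        assert hits >= 95

    def test_forced_must_be_listed(self, rng):
        df = sim_exponential(rng, 50, {"x1": ("binary", 0.5)})
        with pytest.raises(ValueError):
            backward_elimination(df, ["x1"], forced="sig")


class TestCompareHazardModels:
    def test_swap_negates_delta_keeps_p(self, rng):
        df = sim_exponential(rng, 400, {"a": ("binary", 0.8), "b": ("binary", 0.1)})
        r1 = compare_hazard_models(df, "a", "b")
        r2 = compare_hazard_models(df, "b", "a")
        assert r1.delta == pytest.approx(-r2.delta, abs=1e-10)
        assert r1.p == pytest.approx(r2.p, abs=1e-10)

    def test_identical_calls_degenerate(self, rng):
        df = sim_exponential(rng, 100, {"a": ("binary", 0.5)})
        df["b"] = df["a"]
        with pytest.raises(ValueError, match="identical"):
            compare_hazard_models(df, "a", "b")

    def test_near_identical_null_calls_small_delta(self, rng):
        df = sim_exponential(rng, 500, {"a": ("binary", 0.0)})
        df["b"] = df["a"]
        flip = df.index[3]
        df.loc[flip, "b"] = 1.0 - df.loc[flip, "b"]
        res = compare_hazard_models(df, "a", "b")
        # near-collinearity inflates the coefficient variance, so the
        # meaningful check is on the standardized difference
        assert abs(res.z) < 1.5
        assert res.p > 0.2

    def test_informative_beats_random_classifier(self):
        """Planted HR 2.0: the informative predictor's coefficient exceeds
        the random one's (p < 0.05) in >= 80% of seeded replicates."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(3000 + seed)
            df = sim_exponential(rng, 1000, {"info": ("binary", np.log(2.0)),
                                             "rand": ("binary", 0.0)})
            res = compare_hazard_models(df, "info", "rand")
            if res.p < 0.05:
                hits += 1
        assert hits >= 8


class TestPrepareCovariates:
    def test_codings(self, small_cohort):
        _, _, clinical = small_cohort
        X = prepare_covariates(clinical)
        assert set(X["t_class"].dropna().unique()) <= {1.0, 2.0, 3.0, 4.0}
        assert X["female"].isin([0.0, 1.0]).all()
        rect = clinical["site"] == "rectum"
        assert X.loc[rect, "left_sided"].isna().all()
        assert X["pni"].isna().mean() == clinical["pni"].isna().mean()
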