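import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ivuscal.survival import (build_multivariate, cif_estimate, cox_fit,
                              cox_partial_loglik, km_estimate, linreg_fit,
                              logrank_test, schoenfeld_check)


def _events(times, causes, ids=None):
    return pd.DataFrame({
        "id": ids if ids is not None else np.arange(len(times)),
        "time_days": np.asarray(times, float),
        "cause": causes,
        "target_vessel": [False] * len(times),
    })


def _exp_group(rng, n, rate, cause="death", censor_at=50.0):
    t = rng.exponential(1.0 / rate, n)
    obs = t < censor_at
    return _events(np.minimum(t, censor_at),
                   np.where(obs, cause, "censored"))


class TestKaplanMeier:
    def test_three_subject_closed_form(self):
        ev = _events([1, 2, 3], ["death", "death", "censored"])
        km = km_estimate(ev, {"death"})
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2) == pytest.approx(1 / 3)
        assert km.survival_at(3) == pytest.approx(1 / 3)

    def test_no_events_survival_stays_one(self):
        ev = _events([5, 6, 7], ["censored"] * 3)
        km = km_estimate(ev, {"death"})
        assert km.survival_at(100) == 1.0

    def test_all_events_reach_zero(self):
        ev = _events([1, 2, 3, 4], ["death"] * 4)
        km = km_estimate(ev, {"death"})
        assert km.survival_at(4) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(_events([], []), {"death"})

    def test_other_causes_censor(self):
        ev = _events([1, 2], ["mi", "death"])
        km = km_estimate(ev, {"death"})
        assert km.survival_at(1) == pytest.approx(1.0)
        assert km.survival_at(2) == pytest.approx(0.0)


class TestLogrank:
    def test_identical_groups_null(self):
        ev = _events([1, 2, 3, 4], ["death", "death", "censored", "death"])
        res = logrank_test(ev, ev.copy())
        assert res["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert res["p"] == pytest.approx(1.0)

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(1)
        a = _exp_group(rng, 200, rate=0.5)
        b = _exp_group(rng, 200, rate=0.1)
        assert logrank_test(a, b)["p"] < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_events([], []), _events([1], ["death"]))

    def test_type_i_error_calibrated_under_null(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = _exp_group(rng, 30, rate=0.1)
            b = _exp_group(rng, 30, rate=0.1)
            rejections += logrank_test(a, b)["p"] < 0.05
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3 * se


class TestCumulativeIncidence:
    def test_single_cause_reduces_to_one_minus_km(self):
        rng = np.random.default_rng(3)
        ev = _exp_group(rng, 80, rate=0.05)
        cif = cif_estimate(ev, {"death"})
        km = km_estimate(ev, {"death"})
        for t in cif.times:
            assert cif.incidence_at(t) == pytest.approx(1 - km.survival_at(t),
                                                        abs=1e-12)

    def test_two_causes_no_censoring_sum_to_one(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(10, 60)
        causes = np.where(rng.random(60) < 0.4, "death", "mi")
        cif = cif_estimate(_events(t, causes), {"death", "mi"})
        assert cif.all_cause_incidence[-1] == pytest.approx(1.0)

    def test_four_subject_hand_worked_example(self):
        # death@1, mi@2, censored@3, death@4:
        #   CIF_death(1)=1/4; CIF_mi(2)=3/4*1/3=1/4;
        #   S(3-)=1/2; death@4: CIF_death(4)=1/4+1/2=3/4
        ev = _events([1, 2, 3, 4], ["death", "mi", "censored", "death"])
        cif = cif_estimate(ev, {"death", "mi"})
        assert cif.incidence_at(1, "death") == pytest.approx(1 / 4)
        assert cif.incidence_at(3, "death") == pytest.approx(1 / 4)
        assert cif.incidence_at(2, "mi") == pytest.approx(1 / 4)
        assert cif.incidence_at(4, "death") == pytest.approx(3 / 4)
        assert cif.incidence_at(4) == pytest.approx(1.0)

    def test_sum_of_causes_equals_composite(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(10, 100)
        causes = rng.choice(["death", "mi", "stroke"], 100).astype(object)
        causes[rng.random(100) < 0.3] = "censored"
        cif = cif_estimate(_events(t, causes), {"death", "mi", "stroke"})
        total = sum(cif.incidence_by_cause[c][-1]
                    for c in ("death", "mi", "stroke"))
        assert cif.all_cause_incidence[-1] == pytest.approx(total)
        km = km_estimate(_events(t, causes), {"death", "mi", "stroke"})
        assert cif.all_cause_incidence[-1] == pytest.approx(
            1 - km.survival_at(cif.times[-1]), abs=1e-10)


class TestCox:
    def test_three_subject_hand_enumerated_partial_likelihood(self):
        # no ties: the partial likelihood is a 2-term product; maximize it
        # by brute force and compare with the fitted coefficient
        times = np.array([1.0, 2.0, 3.0])
        status = np.array([True, True, True])
        x = np.array([[1.0], [0.0], [1.0]])

        def nll(b):
            return -cox_partial_loglik(np.atleast_1d(b), times, status, x)

        brute = optimize.minimize_scalar(nll, bounds=(-5, 5), method="bounded")
        ev = _events(times, ["death"] * 3)
        fit = cox_fit(ev, pd.DataFrame({"id": ev["id"], "x": x[:, 0]}),
                      {"death"})
        assert fit.coefficients["x"] == pytest.approx(brute.x, abs=1e-4)
        # analytic check of the hand-written likelihood itself at beta=0
        assert cox_partial_loglik(np.array([0.0]), times, status, x) == \
            pytest.approx(math.log(1 / 3) + math.log(1 / 2))

    def test_gradient_vanishes_at_reported_optimum(self):
        rng = np.random.default_rng(6)
        n = 120
        x = rng.normal(size=(n, 2))
        t = rng.exponential(1.0 / (0.05 * np.exp(x @ [0.7, -0.3])))
        ev = _events(t, ["death"] * n)
        cov = pd.DataFrame({"id": ev["id"], "a": x[:, 0], "b": x[:, 1]})
        fit = cox_fit(ev, cov, {"death"})
        beta = fit.coefficients.to_numpy()
        eps = 1e-6
        grad = np.array([
            (cox_partial_loglik(beta + eps * e, t, np.ones(n, bool), x)
             - cox_partial_loglik(beta - eps * e, t, np.ones(n, bool), x))
            / (2 * eps)
            for e in np.eye(2)])
        assert np.linalg.norm(grad) < 1e-6

    def test_large_sample_recovery_of_hr_two(self):
        rng = np.random.default_rng(8)
        n = 2000
        grp = rng.random(n) < 0.5
        t = rng.exponential(1.0 / (0.02 * np.exp(math.log(2.0) * grp)))
        ev = _events(np.minimum(t, 100),
                     np.where(t < 100, "death", "censored"))
        fit = cox_fit(ev, pd.DataFrame({"id": ev["id"], "grp": grp.astype(float)}),
                      {"death"})
        assert 1.8 < fit.hr["grp"] < 2.2
        assert fit.ci_low["grp"] < fit.hr["grp"] < fit.ci_high["grp"]

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(9)
        logs = []
        for _ in range(20):
            n = 150
            x = rng.normal(size=n)
            t = rng.exponential(10, n)
            ev = _events(t, ["death"] * n)
            fit = cox_fit(ev, pd.DataFrame({"id": ev["id"], "x": x}), {"death"})
            logs.append(fit.coefficients["x"])
        assert abs(np.mean(logs)) < 3 * np.std(logs) / math.sqrt(20)

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(10)
        n = 60
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x)))
        ev = _events(t, ["death"] * n)
        cov = pd.DataFrame({"id": ev["id"], "x": x})
        efron = cox_fit(ev, cov, {"death"}, ties_method="efron")
        breslow = cox_fit(ev, cov, {"death"}, ties_method="breslow")
        assert efron.coefficients["x"] == pytest.approx(
            breslow.coefficients["x"], abs=1e-5)

    def test_competing_causes_censor_at_their_time(self):
        # the cause-specific fit must ignore competing events as events
        ev = _events([1, 2, 3, 4], ["death", "mi", "death", "censored"])
        cov = pd.DataFrame({"id": ev["id"], "x": [1.0, 0.0, 0.0, 1.0]})
        fit = cox_fit(ev, cov, {"death"})
        assert fit.n_events == 2

    def test_no_events_of_cause_rejected(self):
        ev = _events([1, 2], ["censored", "censored"])
        with pytest.raises(ValueError):
            cox_fit(ev, pd.DataFrame({"id": ev["id"], "x": [0.0, 1.0]}), {"death"})

    def test_rank_deficient_design_rejected(self):
        ev = _events([1, 2, 3], ["death"] * 3)
        cov = pd.DataFrame({"id": ev["id"], "x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError):
            cox_fit(ev, cov, {"death"})

    def test_stratified_fit_reports_strata(self):
        rng = np.random.default_rng(12)
        n = 200
        strat = (rng.random(n) < 0.4).astype(float)
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x + 1.0 * strat)))
        ev = _events(t, ["death"] * n)
        cov = pd.DataFrame({"id": ev["id"], "x": x, "s": strat})
        fit = cox_fit(ev, cov, {"death"}, strata="s")
        assert fit.strata_spec == "s"
        assert "s" not in fit.coefficients.index
        assert 0.2 < fit.hr["x"] < 3.0


def _ph_replicate(rng, n=70, beta=0.0):
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
    ev = _events(t, ["death"] * n)
    return ev, pd.DataFrame({"id": ev["id"], "x": x})


def _tv_replicate(rng, n=200, tau=5.0):
    """Effect +1.2 before tau, -1.2 after: strongly time-varying."""
    x = (rng.random(n) < 0.5).astype(float)
    h1 = 0.1 * np.exp(1.2 * x)
    h2 = 0.1 * np.exp(-1.2 * x)
    u = rng.exponential(1.0, n)
    t = np.where(u < h1 * tau, u / h1, tau + (u - h1 * tau) / h2)
    ev = _events(t, ["death"] * n)
    return ev, pd.DataFrame({"id": ev["id"], "x": x})


class TestSchoenfeld:
    def test_type_i_error_calibrated_under_proportional_hazards(self):
        rng = np.random.default_rng(21)
        n_rep, rejections = 500, 0
        for _ in range(n_rep):
            ev, cov = _ph_replicate(rng)
            fit = cox_fit(ev, cov, {"death"})
            rejections += schoenfeld_check(fit).loc["x", "p"] < 0.05
        se = math.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rejections / n_rep - 0.05) < 3 * se

    def test_power_against_time_varying_effect(self):
        rng = np.random.default_rng(22)
        n_rep, rejections = 100, 0
        for _ in range(n_rep):
            ev, cov = _tv_replicate(rng)
            fit = cox_fit(ev, cov, {"death"})
            rejections += schoenfeld_check(fit).loc["x", "p"] < 0.05
        assert rejections / n_rep > 0.5

    def test_reports_correlation_and_p(self):
        rng = np.random.default_rng(23)
        ev, cov = _ph_replicate(rng, n=100)
        fit = cox_fit(ev, cov, {"death"})
        out = schoenfeld_check(fit)
        assert {"correlation", "p"} <= set(out.columns)
        assert -1 <= out.loc["x", "correlation"] <= 1

    def test_constant_covariate_rejected(self):
        ev = _events([1, 2, 3], ["death"] * 3)
        cov = pd.DataFrame({"id": ev["id"], "x": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError):
            fit = cox_fit(ev, cov, {"death"})
            schoenfeld_check(fit)


class TestLinearRegression:
    def test_exact_fit_recovers_slope(self):
        x = np.arange(10.0)
        fit = linreg_fit(2 * x, pd.DataFrame({"x": x}))
        assert fit.coefficients["x"] == pytest.approx(2.0)
        assert np.allclose(fit.residuals, 0)

    def test_intercept_only_returns_mean(self):
        y = np.array([1.0, 2.0, 6.0])
        fit = linreg_fit(y, pd.DataFrame(index=range(3)))
        assert fit.coefficients["const"] == pytest.approx(y.mean())

    def test_rank_deficiency_names_columns(self):
        x = np.arange(8.0)
        design = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="b|a"):
            linreg_fit(np.ones(8), design)

    def test_ci_symmetric_about_estimate(self):
        rng = np.random.default_rng(30)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        fit = linreg_fit(y, pd.DataFrame({"x": x}))
        mid = (fit.ci_low["x"] + fit.ci_high["x"]) / 2
        assert mid == pytest.approx(fit.coefficients["x"])


class TestScreening:
    def test_selection_set_is_exactly_p_below_threshold(self):
        rng = np.random.default_rng(31)
        n = 120
        cand = pd.DataFrame(rng.normal(size=(n, 6)),
                            columns=[f"c{i}" for i in range(6)])
        y = 0.3 * cand["c0"] + 0.1 * cand["c3"] + rng.normal(size=n)
        res = build_multivariate(y.to_numpy(), cand)
        import statsmodels.api as sm
        for rec in res.selection_log.itertuples():
            X = sm.add_constant(cand[[rec.candidate]])
            p = sm.OLS(y, X).fit().pvalues[rec.candidate]
            assert rec.univariate_p == pytest.approx(p)
            assert rec.selected == (p < 0.1)
        selected = set(res.selection_log.loc[res.selection_log["selected"],
                                             "candidate"])
        assert set(res.fit.coefficients.index) == selected | {"const"}

    def test_boundary_strictly_below_threshold(self):
        # hunt two replicates whose univariate p falls on either side of 0.1
        rng = np.random.default_rng(32)
        seen_in, seen_out = False, False
        for _ in range(400):
            x = rng.normal(size=40)
            y = 0.25 * x + rng.normal(size=40)
            res = build_multivariate(y, pd.DataFrame({"x": x}))
            p = res.selection_log.loc[0, "univariate_p"]
            sel = res.selection_log.loc[0, "selected"]
            if 0.09 < p < 0.1:
                assert sel
                seen_in = True
            elif 0.1 <= p < 0.11:
                assert not sel
                seen_out = True
            if seen_in and seen_out:
                break
        assert seen_in and seen_out

    def test_pure_noise_inclusion_fraction_near_ten_percent(self):
        rng = np.random.default_rng(33)
        n_rep, n, k = 300, 100, 4
        included = 0
        for _ in range(n_rep):
            cand = pd.DataFrame(rng.normal(size=(n, k)),
                                columns=[f"c{i}" for i in range(k)])
            y = rng.normal(size=n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = build_multivariate(y, cand)
            included += int(res.selection_log["selected"].sum())
        frac = included / (n_rep * k)
        se = math.sqrt(0.1 * 0.9 / (n_rep * k))
        assert abs(frac - 0.1) < 3 * se

    def test_no_candidate_passing_gives_intercept_only_with_warning(self):
        y = np.array([1.0, 1.0, 0.9, 0.9, 1.1, 1.1])  # orthogonal to x
        cand = pd.DataFrame({"x": [0, 1, 0, 1, 0, 1.0]})
        with pytest.warns(UserWarning, match="no candidate"):
            res = build_multivariate(y, cand)
        assert list(res.fit.coefficients.index) == ["const"]
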