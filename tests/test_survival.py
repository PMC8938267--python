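import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from postacute.survival import (aalen_johansen, censor_at, coxph,
                                episode_split, estimate_cif, excess_burden,
                                fit_time_varying, fit_weighted_cox)


def _sim_cox_data(n=2500, beta=0.6, seed=1, ties=False, weights=True):
    rng = np.random.default_rng(seed)
    g = (rng.random(n) < 0.5).astype(float)
    x2 = rng.normal(size=n)
    t = rng.exponential(1 / (2e-3 * np.exp(beta * g + 0.3 * x2)))
    c = np.minimum(t, 400 + rng.random(n))
    e = (t <= c).astype(int)
    if ties:
        c = np.ceil(c / 10) * 10
    w = rng.uniform(0.3, 3.0, n) if weights else np.ones(n)
    return pd.DataFrame({"time": c, "event": e, "g": g, "x2": x2, "w": w})


def _brute_force_efron_loglik(beta, X, time, event, weights, entry=None):
    """Naive O(n^2) weighted Efron partial log-likelihood with explicit
    risk-set loops — the independent oracle for the vectorized fitter."""
    beta = np.atleast_1d(beta)
    s = np.zeros(len(time)) if entry is None else np.asarray(entry, float)
    lp = X @ beta
    r = weights * np.exp(lp)
    ll = 0.0
    for u in np.unique(time[event > 0]):
        at_risk = (time >= u) & (s < u)
        D = (time == u) & (event > 0)
        d = int(D.sum())
        wD = weights[D].sum()
        for l in range(d):
            denom = r[at_risk].sum() - (l / d) * r[D].sum()
            ll -= (wD / d) * np.log(denom)
        ll += (weights[D] * lp[D]).sum()
    return ll


class TestCoxCore:
    def test_matches_lifelines_tie_free(self):
        from lifelines import CoxPHFitter
        df = _sim_cox_data()
        fit = coxph(df[["g", "x2"]].to_numpy(), df["time"], df["event"], df["w"])
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df.rename(columns={"time": "T", "event": "E"}),
                    "T", "E", weights_col="w", robust=True)
        np.testing.assert_allclose(fit.params, cph.params_.values, atol=2e-5)
        np.testing.assert_allclose(fit.robust_se, cph.standard_errors_.values,
                                   rtol=1e-4)

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter
        df = _sim_cox_data(ties=True)
        fit = coxph(df[["g", "x2"]].to_numpy(), df["time"], df["event"], df["w"])
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df.rename(columns={"time": "T", "event": "E"}),
                    "T", "E", weights_col="w", robust=True)
        np.testing.assert_allclose(fit.params, cph.params_.values, atol=2e-5)
        # Efron-averaged residual approximation under ties: agree within 2%
        np.testing.assert_allclose(fit.robust_se, cph.standard_errors_.values,
                                   rtol=2e-2)

    def test_matches_brute_force_partial_likelihood(self):
        """7-person tie-free fixture: the vectorized Newton solution equals
        the argmax of an explicitly coded risk-set-loop likelihood."""
        X = np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0], [0.0]])
        t = np.array([3.0, 5.0, 9.0, 2.0, 4.0, 8.0, 10.0])
        e = np.array([1, 1, 0, 1, 1, 1, 0])
        w = np.array([1.0, 2.0, 1.0, 1.5, 1.0, 0.5, 2.0])
        fit = coxph(X, t, e, w)
        opt = minimize(lambda b: -_brute_force_efron_loglik(b, X, t, e, w),
                       x0=[0.0], method="BFGS")
        assert fit.params[0] == pytest.approx(opt.x[0], abs=1e-4)

    def test_tied_fixture_matches_brute_force(self):
        X = np.array([[1.0], [1.0], [1.0], [0.0], [0.0], [0.0]])
        t = np.array([4.0, 4.0, 7.0, 4.0, 6.0, 7.0])
        e = np.array([1, 1, 1, 1, 0, 1])
        w = np.array([1.0, 2.0, 1.0, 1.0, 2.0, 1.0])
        fit = coxph(X, t, e, w)
        opt = minimize(lambda b: -_brute_force_efron_loglik(b, X, t, e, w),
                       x0=[0.0], method="BFGS")
        assert fit.params[0] == pytest.approx(opt.x[0], abs=1e-4)

    def test_delayed_entry_matches_brute_force(self):
        """6-episode time-varying fixture: risk sets restricted to
        start < t <= stop, verified against the explicit-loop oracle."""
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 0.0],
                      [0.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
        start = np.array([0.0, 5.0, 0.0, 0.0, 3.0, 0.0])
        stop = np.array([5.0, 12.0, 8.0, 3.0, 9.0, 11.0])
        e = np.array([0, 1, 1, 0, 1, 1])
        w = np.array([1.0, 1.0, 2.0, 1.5, 1.5, 1.0])
        fit = coxph(X, stop, e, w, entry=start)
        opt = minimize(
            lambda b: -_brute_force_efron_loglik(b, X, stop, e, w, entry=start),
            x0=[0.0, 0.0], method="BFGS")
        np.testing.assert_allclose(fit.params, opt.x, atol=1e-4)

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            coxph(np.ones((3, 1)), [1.0, 2.0, 3.0], [0, 0, 0])


class TestHazardInterface:
    def test_null_data_covers_one(self):
        df = _sim_cox_data(beta=0.0, seed=5, weights=False)
        df["group"] = np.where(df["g"] > 0, "exposed", "contemporary")
        r = fit_weighted_cox(df)
        assert r.ci95[0] < 1.0 < r.ci95[1]
        assert not r.significant

    def test_exponential_rate_ratio_oracle(self):
        """Exponential data with hazard ratio 2: the Cox estimate agrees
        with the closed-form exponential MLE (event-count / person-time
        ratio) within joint sampling error."""
        df = _sim_cox_data(n=5000, beta=np.log(2.0), seed=7, weights=False)
        df["group"] = np.where(df["g"] > 0, "exposed", "contemporary")
        r = fit_weighted_cox(df)
        g = df["g"] > 0
        mle = ((df.loc[g, "event"].sum() / df.loc[g, "time"].sum())
               / (df.loc[~g, "event"].sum() / df.loc[~g, "time"].sum()))
        assert r.ci95[0] < 2.0 < r.ci95[1]
        assert np.log(r.hr) == pytest.approx(np.log(mle), abs=0.03)

    def test_constant_weight_scale_invariance(self):
        df = _sim_cox_data(seed=9)
        df["group"] = np.where(df["g"] > 0, "exposed", "contemporary")
        r1 = fit_weighted_cox(df, np.ones(len(df)))
        r2 = fit_weighted_cox(df, np.full(len(df), 7.3))
        assert r1.hr == pytest.approx(r2.hr, rel=1e-9)
        assert r1.log_hr_se == pytest.approx(r2.log_hr_se, rel=1e-9)

    def test_empty_stratum_identified(self):
        df = _sim_cox_data(seed=11, weights=False)
        df["group"] = np.where(df["g"] > 0, "exposed", "contemporary")
        df.loc[df["g"] == 0, "event"] = 0
        with pytest.raises(ValueError, match="control"):
            fit_weighted_cox(df)


def _aj_brute_force(time, event, death, weights, horizon):
    """Naive step-by-step Aalen-Johansen recursion."""
    t = np.asarray(time, float)
    e = np.asarray(event, float)
    d = np.asarray(death, float)
    w = np.asarray(weights, float)
    cif, surv = 0.0, 1.0
    for u in sorted(set(t[((e > 0) | (d > 0))])):
        if u > horizon:
            break
        at_risk = w[t >= u].sum()
        dn1 = w[(t == u) & (e > 0)].sum()
        dnd = w[(t == u) & (d > 0)].sum()
        cif += surv * dn1 / at_risk
        surv *= 1 - (dn1 + dnd) / at_risk
    return cif


class TestAalenJohansen:
    def test_reduces_to_km_without_competing_risk(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(1)
        t = np.ceil(rng.exponential(200, 300))
        e = (rng.random(300) < 0.7).astype(int)
        t = np.maximum(t, 1)
        cif = aalen_johansen(t, e, np.zeros(300), horizon_days=150.0)
        km = KaplanMeierFitter().fit(t, e)
        assert cif == pytest.approx(1 - km.survival_function_at_times(150.0).iloc[0],
                                    abs=1e-12)

    def test_matches_lifelines_aalen_johansen(self):
        from lifelines import AalenJohansenFitter
        rng = np.random.default_rng(2)
        t = np.maximum(rng.exponential(150, 400), 0.01)  # tie-free
        cause = rng.choice([0, 1, 2], 400, p=[0.3, 0.4, 0.3])
        cif = aalen_johansen(t, (cause == 1).astype(int),
                             (cause == 2).astype(int), horizon_days=120.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ajf = AalenJohansenFitter(calculate_variance=False, seed=0)
            ajf.fit(t, cause, event_of_interest=1)
        ours = cif
        theirs = float(ajf.cumulative_density_.loc[
            ajf.cumulative_density_.index <= 120.0].iloc[-1, 0])
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_weighted_ten_person_fixture_matches_hand_recursion(self):
        t = np.array([2, 3, 3, 5, 6, 7, 8, 8, 9, 10], dtype=float)
        e = np.array([1, 0, 1, 0, 1, 0, 1, 0, 0, 0])
        d = np.array([0, 1, 0, 0, 0, 1, 0, 0, 1, 0])
        w = np.array([1.0, 2.0, 1.0, 0.5, 1.5, 1.0, 2.0, 1.0, 0.5, 1.0])
        ours = aalen_johansen(t, e, d, w, horizon_days=8.0)
        oracle = _aj_brute_force(t, e, d, w, 8.0)
        assert ours == pytest.approx(oracle, abs=1e-12)
        # frozen value of the hand recursion on this fixture
        assert ours == pytest.approx(0.5, abs=1e-12)

    def test_horizon_beyond_followup_raises(self):
        with pytest.raises(ValueError):
            aalen_johansen([10.0, 20.0], [1, 0], [0, 0], horizon_days=30.0)


class TestBurden:
    def _two_groups(self, n=3000, h1=2e-3, h2=1e-3, seed=3):
        rng = np.random.default_rng(seed)
        te = rng.exponential(1 / h1, 2 * n)
        td = rng.exponential(1 / h2, 2 * n)
        t = np.minimum(np.minimum(te, td), 500.0)
        return pd.DataFrame({
            "person_id": [f"p{i}" for i in range(2 * n)],
            "group": ["exposed"] * n + ["contemporary"] * n,
            "time": t,
            "event": ((te <= td) & (te <= 500)).astype(int),
            "death": ((td < te) & (td <= 500)).astype(int),
        })

    def test_identical_groups_excess_covers_zero(self):
        df = self._two_groups()
        b = excess_burden(df, resamples=200, seed=0)
        assert b.excess_ci[0] < 0 < b.excess_ci[1]
        assert abs(b.excess_burden) < 20

    def test_point_estimate_is_exact_difference(self):
        df = self._two_groups(seed=5)
        b = excess_burden(df, resamples=50, seed=0)
        cifs = estimate_cif(df)
        assert b.excess_burden == pytest.approx(
            cifs["exposed"] - cifs["control"], abs=1e-12)
        assert b.burden_exposed == pytest.approx(cifs["exposed"], abs=1e-12)

    def test_closed_form_competing_exponentials(self):
        df = self._two_groups(n=40_000, seed=6)
        cifs = estimate_cif(df[df["group"] == "exposed"]
                            .assign(group="exposed")
                            .pipe(lambda d: pd.concat(
                                [d, df[df["group"] != "exposed"]])))
        h1, h2 = 2e-3, 1e-3
        theory = 1000 * h1 / (h1 + h2) * (1 - np.exp(-(h1 + h2) * 365))
        se = 1000 * np.sqrt(theory / 1000 * (1 - theory / 1000) / 40_000)
        assert abs(cifs["exposed"] - theory) < 3 * se

    def test_too_few_resamples_rejected(self):
        with pytest.raises(ValueError):
            excess_burden(self._two_groups(), resamples=1)


class TestCensorAt:
    def _sub(self):
        entry = pd.Timestamp("2020-05-01")
        return pd.DataFrame({
            "person_id": ["a", "b", "c", "d"],
            "group": ["exposed"] * 4,
            "entry_date": [entry] * 4,
            "time": [100.0, 200.0, 150.0, 50.0],
            "event": [1, 1, 0, 0],
            "death": [0, 0, 1, 0],
        })

    def test_no_dates_is_identity(self):
        sub = self._sub()
        out, dropped = censor_at(sub, pd.Series(dtype="datetime64[ns]"))
        assert dropped == 0
        pd.testing.assert_frame_equal(out, sub)

    def test_censoring_before_event_removes_it(self):
        sub = self._sub()
        dates = pd.Series({"a": pd.Timestamp("2020-06-01")})  # entry+31 < 100
        out, _ = censor_at(sub, dates)
        row = out.set_index("person_id").loc["a"]
        assert row["event"] == 0 and row["time"] == 31

    def test_person_time_matches_hand_computation(self):
        # a: censored day 31; b: vaccinated day 250 after exit -> unchanged;
        # c: vaccinated pre-entry -> dropped
        sub = self._sub()
        dates = pd.Series({"a": pd.Timestamp("2020-06-01"),
                           "b": pd.Timestamp("2021-01-06"),
                           "c": pd.Timestamp("2020-04-01")})
        out, dropped = censor_at(sub, dates)
        assert dropped == 1
        assert out["time"].sum() == 31 + 200 + 50

    def test_events_after_censor_not_counted(self):
        sub = self._sub()
        dates = pd.Series({"b": pd.Timestamp("2020-07-01")})  # day 61 < 200
        out, _ = censor_at(sub, dates)
        assert out.set_index("person_id").loc["b", "event"] == 0


class TestTimeVarying:
    def _sub(self, n=800, seed=4):
        rng = np.random.default_rng(seed)
        entry = pd.Timestamp("2020-05-01")
        t = np.maximum(rng.exponential(300, n), 1.0)
        c = np.minimum(t, 365.0)
        return pd.DataFrame({
            "person_id": [f"p{i}" for i in range(n)],
            "group": rng.choice(["exposed", "contemporary"], n),
            "entry_date": [entry] * n,
            "time": np.round(c, 3),
            "event": (t <= 365).astype(int),
            "death": 0,
        })

    def test_no_switches_equals_plain_cox(self):
        sub = self._sub()
        plain = fit_weighted_cox(sub)
        tv = fit_time_varying(sub, None, pd.Series(dtype="datetime64[ns]"))
        assert tv.hr == pytest.approx(plain.hr, rel=1e-6)

    def test_everyone_switched_at_entry_reports_aliasing(self):
        sub = self._sub(n=50)
        dates = pd.Series(pd.Timestamp("2020-04-01"),
                          index=sub["person_id"])
        with pytest.raises(ValueError, match="alias"):
            fit_time_varying(sub, None, dates)

    def test_episode_split_risk_sets_match_hand_enumeration(self):
        sub = pd.DataFrame({
            "person_id": ["a", "b", "c"],
            "group": ["exposed", "contemporary", "exposed"],
            "entry_date": [pd.Timestamp("2020-05-01")] * 3,
            "time": [100.0, 80.0, 60.0],
            "event": [1, 1, 0],
            "death": [0, 0, 0],
        })
        # b switches on day 30, a never, c pre-entry
        dates = pd.Series({"b": pd.Timestamp("2020-05-31"),
                           "c": pd.Timestamp("2020-04-01")})
        long = episode_split(sub, dates)
        # hand enumeration: a -> one unswitched episode [0,100);
        # b -> [0,30) unswitched + [30,80) switched-with-event; c -> [0,60) switched
        assert len(long) == 4
        b_rows = long[long["id"] == 1]
        assert b_rows["stop"].tolist() == [30.0, 80.0]
        assert b_rows["event"].tolist() == [0.0, 1.0]
        assert b_rows["switched"].tolist() == [0.0, 1.0]
        c_row = long[long["id"] == 2].iloc[0]
        assert c_row["switched"] == 1.0 and c_row["stop"] == 60.0
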