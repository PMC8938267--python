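import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from postacute import SimConfig, generate_cohort, inject_history
from postacute.cohort import apply_landmark, build_subcohort
from postacute.config import CohortSpec, RunConfig
from postacute.pipeline import prepare_persons


def _null_config(**kw):
    base = dict(
        n_exposed=4000, n_contemporary=4000, n_historical=50,
        n_noise_codes_per_domain=(5, 5, 2),
        true_log_hr={"outcome": 0.0},
        baseline_hazard={"outcome": 4.0e-4},
        confounder_effect_on_exposure=(0,) * 5,
        confounder_effect_on_hazard=(0,) * 5,
        seed=7,
    )
    base.update(kw)
    return SimConfig(**base)


def test_determinism_same_seed_same_tables():
    cfg = dict(n_exposed=400, n_contemporary=400, n_historical=400,
               n_noise_codes_per_domain=(8, 8, 3), seed=11)
    a = generate_cohort(SimConfig(**cfg))
    b = generate_cohort(SimConfig(**cfg))
    assert_frame_equal(a.persons, b.persons)
    assert_frame_equal(a.events, b.events)
    assert_frame_equal(a.codes, b.codes)
    c = generate_cohort(SimConfig(**{**cfg, "seed": 12}))
    assert not a.persons["age"].equals(c.persons["age"])


def test_null_config_rates_equal_between_groups():
    tables = generate_cohort(_null_config())
    ev = tables.events.merge(tables.persons[["person_id", "group", "anchor"]])
    post = ev[ev["event_date"] >= ev["anchor"]]
    counts = post.groupby("group")["person_id"].nunique()
    p1 = counts.get("exposed", 0) / 4000
    p0 = counts.get("contemporary", 0) / 4000
    se = np.sqrt(p1 * (1 - p1) / 4000 + p0 * (1 - p0) / 4000)
    assert abs(p1 - p0) < 3.5 * se


def test_zero_death_hazard_gives_no_death_dates():
    tables = generate_cohort(_null_config(death_hazard=0.0))
    assert tables.persons["death_date"].isna().all()


def test_crude_rate_ratio_matches_exponential_oracle():
    """No confounding, true log HR beta: the crude event/person-time rate
    ratio in the incident subcohort must match exp(beta) within the
    closed-form exponential-model CI (1/e1 + 1/e0 log-variance)."""
    beta = np.log(2.0)
    cfg = _null_config(n_exposed=15_000, n_contemporary=15_000,
                       true_log_hr={"outcome": float(beta)}, seed=3)
    tables = generate_cohort(cfg)
    spec = CohortSpec()
    prep = prepare_persons(tables, RunConfig(k_highdim=0, seed=3), spec)
    sub = build_subcohort(prep, tables.events, "outcome", spec).data
    g = sub["group"] == "exposed"
    rate = lambda m: sub.loc[m, "event"].sum() / sub.loc[m, "time"].sum()
    e1, e0 = sub.loc[g, "event"].sum(), sub.loc[~g, "event"].sum()
    log_rr = np.log(rate(g) / rate(~g))
    se = np.sqrt(1 / e1 + 1 / e0)
    assert abs(log_rr - beta) < 3 * se


def test_cumulative_incidence_matches_exponential_closed_form():
    """Single enrollment date, no deaths, constant hazard h: empirical
    12-month incidence equals 1 - exp(-h*365) within binomial error."""
    h = 5.0e-4
    cfg = _null_config(n_exposed=20_000, n_contemporary=50, death_hazard=0.0,
                       baseline_hazard={"outcome": h},
                       enrollment_dates=(["2020-05-01"], [1.0]),
                       vaccination_rate=0.0, seed=9)
    tables = generate_cohort(cfg)
    spec = CohortSpec()
    prep = prepare_persons(tables, RunConfig(seed=9), spec)
    sub = build_subcohort(prep, tables.events, "outcome", spec).data
    sub = sub[sub["group"] == "exposed"]
    p_hat = ((sub["event"] == 1) & (sub["time"] <= 365)).mean()
    p_true = 1 - np.exp(-h * 365)
    se = np.sqrt(p_true * (1 - p_true) / len(sub))
    assert abs(p_hat - p_true) < 3.5 * se


def test_event_dates_lie_inside_simulated_window():
    tables = generate_cohort(_null_config())
    end = pd.Timestamp(tables.config.admin_censor_date)
    start = (tables.persons["anchor"].min()
             - pd.Timedelta(days=tables.config.clock_back_days))
    assert tables.events["event_date"].max() <= end
    assert tables.events["event_date"].min() >= start
    assert set(tables.codes["domain"]) <= {"diagnosis", "medication", "laboratory"}


def test_controls_carry_no_t0():
    tables = generate_cohort(_null_config())
    grp = tables.persons["group"]
    assert tables.persons.loc[grp == "exposed", "t0"].notna().all()
    assert tables.persons.loc[grp != "exposed", "t0"].isna().all()


@pytest.mark.parametrize("bad", [
    dict(n_exposed=0),
    dict(care_setting_probs=(0.5, 0.5, 0.5)),
    dict(missing_rate=1.5),
    dict(baseline_hazard={"outcome": -1e-4}),
    dict(true_log_hr={"other": 0.1}),  # no matching baseline hazard
])
def test_invalid_configs_rejected(bad):
    base = dict(true_log_hr={"outcome": 0.0},
                baseline_hazard={"outcome": 1e-4})
    base.update(bad)
    with pytest.raises(ValueError):
        SimConfig(**base)


class TestInjectHistory:
    def test_zero_fraction_is_identity(self, small_tables):
        out = inject_history(small_tables, "stroke", 0.0, seed=1)
        assert out is small_tables

    def test_exact_count_flagged(self):
        tables = generate_cohort(_null_config(n_exposed=500, n_contemporary=250,
                                              n_historical=250))
        out = inject_history(tables, "outcome", 0.3, seed=5)
        pre = out.events.merge(out.persons[["person_id", "anchor"]])
        in_window = ((pre["event_date"] < pre["anchor"])
                     & (pre["event_date"] >= pre["anchor"] - pd.Timedelta(days=365)))
        assert in_window.sum() >= 300  # 300 injected plus any natural history
        # injected ids are an exact 30% draw
        assert len(out.events) >= len(tables.events)

    def test_full_fraction_empties_subcohort(self):
        tables = generate_cohort(_null_config(n_exposed=300, n_contemporary=300,
                                              n_historical=50))
        out = inject_history(tables, "outcome", 1.0, seed=2)
        spec = CohortSpec()
        prep = prepare_persons(out, RunConfig(seed=2), spec)
        sub = build_subcohort(prep, out.events, "outcome", spec)
        assert len(sub) == 0

    def test_unknown_outcome_raises(self, small_tables):
        with pytest.raises(KeyError):
            inject_history(small_tables, "nonexistent", 0.1, seed=1)
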