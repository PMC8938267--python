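import numpy as np
import pandas as pd
import pytest

from postacute import SimConfig, generate_cohort

T0 = pd.Timestamp("2020-04-01")
ENTRY = T0 + pd.Timedelta(days=30)


@pytest.fixture(scope="session")
def small_tables():
    """A small confounded cohort shared across tests (seeded)."""
    cfg = SimConfig(
        n_exposed=1500, n_contemporary=1500, n_historical=1500,
        n_noise_codes_per_domain=(15, 15, 6),
        true_log_hr={"stroke": float(np.log(1.8)), "mi": 0.0},
        baseline_hazard={"stroke": 3.0e-4, "mi": 3.0e-4},
        seed=42,
    )
    return generate_cohort(cfg)


def make_persons(rows):
    """Hand-crafted persons table with the columns the cohort builder needs."""
    base = {
        "group": "exposed", "care_setting": "non_hospitalized",
        "t0": T0, "anchor": T0, "death_date": pd.NaT,
        "vaccination_date": pd.NaT, "flu_vaccine_date": pd.NaT,
    }
    recs = []
    for r in rows:
        rec = dict(base)
        rec.update(r)
        recs.append(rec)
    df = pd.DataFrame(recs)
    for col in ("t0", "anchor", "death_date", "vaccination_date",
                "flu_vaccine_date"):
        df[col] = pd.to_datetime(df[col])
    return df


def make_events(rows):
    df = pd.DataFrame(rows, columns=["person_id", "outcome", "event_date"])
    df["event_date"] = pd.to_datetime(df["event_date"])
    return df


@pytest.fixture
def toy_cohort():
    """Ten-person fixture with every exclusion/censoring case enumerated by
    hand (see test_cohort for the enumeration)."""
    persons = make_persons([
        {"person_id": "p1"},
        {"person_id": "p2"},
        {"person_id": "p3"},
        {"person_id": "p4"},
        {"person_id": "p5", "death_date": "2020-04-20"},   # T0+19
        {"person_id": "p6", "death_date": "2020-05-01"},   # exactly T0+30
        {"person_id": "p7", "death_date": "2020-07-01"},   # entry+61
        {"person_id": "p8", "death_date": "2020-07-15"},   # entry+75
        {"person_id": "p9"},
        {"person_id": "p10"},
    ])
    events = make_events([
        ("p2", "outcome", "2020-06-10"),   # entry+40 -> event
        ("p3", "outcome", "2020-01-15"),   # lookback window -> excluded
        ("p4", "outcome", "2020-04-11"),   # acute window (T0+10)
        ("p8", "outcome", "2020-08-01"),   # after own death -> death wins
        ("p9", "outcome", "2019-03-01"),   # before lookback start
        ("p10", "outcome", "2020-05-01"),  # exactly at entry (acute)
    ])
    return persons, events
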