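"""Analysis-ready cohort construction.

Control T0 assignment from the exposed enrollment distribution, the 30-day
landmark survival filter, and outcome-specific incident subcohorts with
history exclusion and competing-risk bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortSpec


@dataclass
class Subcohort:
    """One outcome's incident analysis table.

    ``data`` has one row per eligible person with columns: person_id, group,
    care_setting, t0, entry_date, time (days from entry, > 0), event (0/1),
    death (0/1 competing event; 0 whenever event = 1).
    """

    outcome: str
    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)


def assign_control_t0(exposed_t0_dates, control_ids, offset_days: int = 0,
                      seed: int = 0) -> pd.Series:
    """Draw a T0 for every control i.i.d. from the empirical exposed T0
    distribution, shifted back ``offset_days`` (730 for the historical group).
    """
    exposed_t0 = pd.to_datetime(pd.Series(list(exposed_t0_dates))).dropna()
    if len(exposed_t0) == 0:
        raise ValueError("exposed T0 date list is empty")
    control_ids = list(control_ids)
    if len(control_ids) == 0:
        raise ValueError("control id list is empty")
    rng = np.random.default_rng(seed)
    pool = exposed_t0.to_numpy("datetime64[D]")
    drawn = pool[rng.integers(0, len(pool), size=len(control_ids))]
    drawn = drawn - np.timedelta64(int(offset_days), "D")
    return pd.Series(pd.to_datetime(drawn), index=control_ids, name="t0")


def apply_landmark(persons: pd.DataFrame, spec: CohortSpec) -> pd.DataFrame:
    """Keep persons alive strictly beyond T0 + landmark_days and set the time
    origin there (``entry_date`` column).  Every record must carry a T0.
    """
    if persons["t0"].isna().any():
        n_bad = int(persons["t0"].isna().sum())
        raise ValueError(f"{n_bad} records lack T0; assign control T0 first")
    out = persons.copy()
    out["entry_date"] = out["t0"] + pd.Timedelta(days=spec.landmark_days)
    end = out["group"].map(lambda g: spec.end_for(g))
    alive = out["death_date"].isna() | (out["death_date"] > out["entry_date"])
    in_followup = out["entry_date"] < end
    return out.loc[alive & in_followup].reset_index(drop=True)


def _first_event_dates(events: pd.DataFrame, outcomes: list[str]) -> pd.Series:
    ev = events[events["outcome"].isin(outcomes)]
    return ev.groupby("person_id")["event_date"].min()


def build_subcohort(persons: pd.DataFrame, events: pd.DataFrame, outcome: str,
                    spec: CohortSpec, components: list[str] | None = None,
                    death_is_event: bool = False) -> Subcohort:
    """Build the incident subcohort for ``outcome``.

    Excludes persons with the outcome in ``[T0 - lookback_days, T0)`` and (by
    default) persons whose first occurrence falls in the acute window
    ``[T0, T0 + landmark_days]`` — they are prevalent at the landmark origin.
    Death acts as a competing risk unless ``death_is_event`` (as for a MACE
    composite, where all-cause mortality is a component event).

    ``components`` lists the component outcomes of a composite; the event is
    the earliest component occurrence.  ``persons`` must already be
    landmarked (carry ``entry_date``).
    """
    if "entry_date" not in persons.columns:
        raise ValueError("apply_landmark must run before build_subcohort")
    outcomes = components if components is not None else [outcome]
    known = set(events["outcome"].unique())
    unknown = [o for o in outcomes if o not in known and o != "death"]
    if not set(outcomes) & (known | {"death"}):
        raise KeyError(f"unknown outcome(s): {unknown or outcomes}")

    first = _first_event_dates(events, outcomes)
    ev_date = persons["person_id"].map(first)

    t0 = persons["t0"]
    lookback_start = t0 - pd.Timedelta(days=spec.lookback_days)
    history = ev_date.notna() & (ev_date >= lookback_start) & (ev_date < t0)
    if spec.acute_window == "exclude":
        acute = ev_date.notna() & (ev_date >= t0) & (ev_date <= persons["entry_date"])
        eligible = ~(history | acute)
        post_event = ev_date.where(ev_date > persons["entry_date"])
    else:  # "retain": acute-window occurrences are ignored, person stays at risk
        eligible = ~history
        post_event = ev_date.where(ev_date > persons["entry_date"])
    kept = persons.loc[eligible].copy()
    post_event = post_event[eligible]
    if len(kept) == 0:
        empty = pd.DataFrame(columns=["person_id", "group", "care_setting",
                                      "t0", "entry_date", "time", "event",
                                      "death"])
        return Subcohort(outcome=outcome, data=empty)

    end = pd.to_datetime(kept["group"].map(lambda g: spec.end_for(g)))
    t_admin = (end - kept["entry_date"]).dt.days.astype(float)
    t_event = (post_event - kept["entry_date"]).dt.days.astype(float)
    t_death = (kept["death_date"] - kept["entry_date"]).dt.days.astype(float)
    t_event = t_event.fillna(np.inf)
    t_death = t_death.fillna(np.inf)
    if death_is_event:
        t_event = np.minimum(t_event, t_death)
        t_death = pd.Series(np.inf, index=kept.index)

    exit_t = np.minimum(np.minimum(t_event, t_death), t_admin)
    event = (t_event <= exit_t) & np.isfinite(t_event)
    death = ~event & (t_death <= exit_t) & np.isfinite(t_death)

    data = pd.DataFrame({
        "person_id": kept["person_id"].to_numpy(),
        "group": kept["group"].to_numpy(),
        "care_setting": kept["care_setting"].to_numpy(),
        "t0": kept["t0"].to_numpy(),
        "entry_date": kept["entry_date"].to_numpy(),
        "time": exit_t.to_numpy() if hasattr(exit_t, "to_numpy") else exit_t,
        "event": event.to_numpy().astype(int),
        "death": death.to_numpy().astype(int),
    })
    data = data[data["time"] > 0].reset_index(drop=True)
    return Subcohort(outcome=outcome, data=data)


def care_setting_partition(subcohort: Subcohort) -> dict[str, pd.DataFrame]:
    """Split the exposed members into mutually exclusive care-setting strata,
    each paired with the full control arm."""
    df = subcohort.data
    controls = df[df["group"] != "exposed"]
    out = {}
    for setting in ("non_hospitalized", "hospitalized", "icu"):
        stratum = df[(df["group"] == "exposed") & (df["care_setting"] == setting)]
        out[setting] = pd.concat([stratum, controls], ignore_index=True)
    return out
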