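"""Control batteries: positive/negative outcome controls and the
negative-exposure (calendar-parity) control.

Each control re-runs the identical pipeline with only the outcome or the
exposure definition substituted, and is judged against its a-priori
expectation under the 95%-CI significance rule."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CohortSpec, RunConfig, config_hash
from .simulate import CohortTables


@dataclass
class ControlSpec:
    kind: str  # positive_outcome | negative_outcome | negative_exposure
    name: str
    expected: str  # significant_gt1 | nonsignificant
    outcome: str | None = None  # outcome controls
    date_field: str = "flu_vaccine_date"  # negative-exposure parity split

    def __post_init__(self) -> None:
        if self.kind not in ("positive_outcome", "negative_outcome",
                             "negative_exposure"):
            raise ValueError(f"unknown control kind {self.kind!r}")
        if self.expected not in ("significant_gt1", "nonsignificant"):
            raise ValueError("every control needs a declared expectation")


def split_by_calendar_parity(persons: pd.DataFrame,
                             date_field: str) -> tuple[pd.Series, int]:
    """Deterministic partition by day-of-month parity of the given date.

    Returns (parity series: 'odd'/'even' indexed like persons with dated rows
    only, count of records excluded for a missing date)."""
    dates = pd.to_datetime(persons[date_field])
    missing = dates.isna()
    day = dates[~missing].dt.day
    parity = pd.Series(np.where(day % 2 == 1, "odd", "even"),
                       index=day.index, name="parity")
    return parity, int(missing.sum())


def parity_pseudo_tables(tables: CohortTables,
                         date_field: str = "flu_vaccine_date") -> CohortTables:
    """Relabel the cohort for the negative-exposure control: the date itself
    becomes T0 and day-of-month parity becomes the exposure contrast
    (odd -> 'exposed', even -> 'contemporary')."""
    persons = tables.persons[tables.persons["group"] != "historical"]
    parity, _ = split_by_calendar_parity(persons, date_field)
    persons = persons.loc[parity.index].copy()
    persons["group"] = np.where(parity == "odd", "exposed", "contemporary")
    persons["t0"] = persons[date_field]
    persons["anchor"] = persons[date_field]
    persons["care_setting"] = "none"
    return CohortTables(persons.reset_index(drop=True), tables.events,
                        tables.codes, tables.config)


def _expectation_met(hr_result, expected: str) -> bool:
    if expected == "significant_gt1":
        return hr_result.significant and hr_result.hr > 1.0
    return not hr_result.significant


def run_battery(specs: list[ControlSpec], tables: CohortTables,
                run_cfg: RunConfig, spec: CohortSpec | None = None,
                outcomes_for_exposure_controls: list[str] | None = None
                ) -> pd.DataFrame:
    """Run every control through the identical pipeline configuration and
    report HR, CI and whether the a-priori expectation was met.

    The configuration hash recorded per row is identical across the battery
    (only the outcome/exposure substitution differs), making the
    "same design, same analysis" property auditable."""
    from .pipeline import analyze_outcome

    spec = spec or CohortSpec()
    base_cfg = dataclasses.replace(run_cfg, run_did=False,
                                   care_setting_stratified=False)
    cfg_hash = config_hash(base_cfg)
    rows = []
    for ctrl in specs:
        if ctrl.kind in ("positive_outcome", "negative_outcome"):
            res, _ = analyze_outcome(tables, ctrl.outcome, base_cfg, spec,
                                     compute_burden=False)
            hits = [(ctrl.outcome, res[0].hazard)]
        else:
            pseudo = parity_pseudo_tables(tables, ctrl.date_field)
            hits = []
            for outcome in (outcomes_for_exposure_controls
                            or tables.config.outcomes):
                res, _ = analyze_outcome(pseudo, outcome, base_cfg, spec,
                                         compute_burden=False)
                hits.append((outcome, res[0].hazard))
        for outcome, hr in hits:
            rows.append({
                "control": ctrl.name, "kind": ctrl.kind, "outcome": outcome,
                "hr": hr.hr, "ci_low": hr.ci95[0], "ci_high": hr.ci95[1],
                "expected": ctrl.expected,
                "met": _expectation_met(hr, ctrl.expected),
                "config_hash": cfg_hash,
            })
    return pd.DataFrame(rows, columns=["control", "kind", "outcome", "hr",
                                       "ci_low", "ci_high", "expected", "met",
                                       "config_hash"])
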