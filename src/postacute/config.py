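"""Configuration objects for the synthetic cohort generator and the pipeline.

All calendar quantities are `numpy.datetime64[D]`-compatible ISO date strings in
configs and `pandas.Timestamp` in memory.  Durations are integer days.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

#: earliest enrollment date of the exposed group
ENROLLMENT_START = "2020-03-01"
#: last enrollment date of the exposed group
ENROLLMENT_END = "2021-01-15"
#: administrative end of follow-up for the exposed / contemporary groups
END_OF_FOLLOWUP = "2021-10-31"
#: calendar offset of the historical (pre-pandemic) control group, in days
HISTORICAL_OFFSET_DAYS = 730

GROUPS = ("exposed", "contemporary", "historical")
CARE_SETTINGS = ("non_hospitalized", "hospitalized", "icu")
CODE_DOMAINS = ("diagnosis", "medication", "laboratory")


def _as_date(x) -> pd.Timestamp:
    return pd.Timestamp(x).normalize()


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The generator emulates a three-group EHR cohort: an exposed group enrolled
    over ``enrollment_start..enrollment_end``, a contemporary control group
    sharing that calendar window, and a historical control group shifted back
    by ``historical_offset_days``.  Confounding is induced by mean shifts of
    latent standard-normal factors in the exposed group
    (``confounder_effect_on_exposure``); the same factors, through their
    observed covariate transforms, enter every cause-specific log hazard
    (``confounder_effect_on_hazard``).  Event times follow piecewise-constant
    (exponential) cause-specific hazards: before T0 everyone is at baseline,
    from T0 the exposed group's hazard is multiplied by ``exp(true_log_hr)``.

    Baseline event rates are not dictated by any external source and are
    deliberately arbitrary defaults in the plausible range for an older,
    comorbid population; override them per study.
    """

    n_exposed: int = 10_000
    n_contemporary: int = 10_000
    n_historical: int = 10_000
    #: optional explicit enrollment distribution: (dates, probabilities).
    #: Default: uniform over the enrollment window.
    enrollment_dates: tuple[Sequence[str], Sequence[float]] | None = None
    enrollment_start: str = ENROLLMENT_START
    enrollment_end: str = ENROLLMENT_END
    #: P(non-hospitalized, hospitalized, ICU) for the exposed acute phase;
    #: defaults follow the reported 131,612 / 16,760 / 5,388 split.
    care_setting_probs: tuple[float, float, float] = (0.8560, 0.1090, 0.0350)
    n_confounders: int = 5
    #: sparse binary code counts per domain (diagnosis, medication, laboratory)
    n_noise_codes_per_domain: tuple[int, int, int] = (540, 543, 62)
    #: outcome -> log hazard ratio of exposure (scalar, or mapping
    #: care-setting -> scalar for graded effects)
    true_log_hr: Mapping[str, float | Mapping[str, float]] = field(
        default_factory=lambda: {"stroke": float(np.log(1.5)), "mi": float(np.log(1.6))}
    )
    #: outcome -> baseline hazard per day
    baseline_hazard: Mapping[str, float] = field(
        default_factory=lambda: {"stroke": 2.0e-5, "mi": 1.5e-5}
    )
    death_hazard: float = 8.0e-5
    #: log hazard ratio of exposure on death (scalar or per care setting)
    death_log_hr: float | Mapping[str, float] = float(np.log(1.3))
    #: mean shifts of the latent confounder factors in the exposed group,
    #: ordered (age, smoking, utilization, adi, bmi); padded/truncated to
    #: n_confounders.  The default leaves the utilization factor
    #: exposure-neutral so the true exposure model stays logistic-linear in
    #: the observed covariate transforms (a latent Poisson-rate tilt would
    #: fall outside the fitted propensity class).
    confounder_effect_on_exposure: tuple[float, ...] = (0.5, 0.3, 0.0, 0.3, 0.2)
    #: log-hazard coefficients of the standardized observed confounders,
    #: same order.
    confounder_effect_on_hazard: tuple[float, ...] = (0.30, 0.25, 0.15, 0.10, 0.10)
    #: MCAR missingness fraction applied to bmi, egfr, sbp, dbp
    missing_rate: float = 0.05
    vaccination_rate: float = 0.40
    #: fraction with an influenza-vaccine date inside the enrollment window
    #: (used by the negative-exposure parity control)
    flu_vaccination_rate: float = 0.50
    admin_censor_date: str = END_OF_FOLLOWUP
    #: days before the enrollment anchor at which the event-hazard clock
    #: starts; the default equals the history lookback so that every pre-T0
    #: event is visible to the history exclusion.  Difference-in-differences
    #: designs need a longer runway (e.g. 1100 d) to populate the pre-period.
    clock_back_days: int = 365
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_exposed", "n_contemporary", "n_historical"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        probs = np.asarray(self.care_setting_probs, dtype=float)
        if probs.min() < 0 or probs.max() > 1 or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("care_setting_probs must lie in [0,1] and sum to 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for rate_name in ("vaccination_rate", "flu_vaccination_rate"):
            r = getattr(self, rate_name)
            if not 0 <= r <= 1:
                raise ValueError(f"{rate_name} must be in [0, 1]")
        if set(self.true_log_hr) - set(self.baseline_hazard):
            raise ValueError("every outcome in true_log_hr needs a baseline_hazard")
        for out, h in self.baseline_hazard.items():
            if h < 0:
                raise ValueError(f"baseline_hazard[{out}] must be >= 0")
        if self.death_hazard < 0:
            raise ValueError("death_hazard must be >= 0")
        if self.enrollment_dates is not None:
            _, p = self.enrollment_dates
            p = np.asarray(p, dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("enrollment date probabilities must be >= 0 and sum to 1")
        if self.clock_back_days < 0:
            raise ValueError("clock_back_days must be >= 0")

    @property
    def outcomes(self) -> list[str]:
        return list(self.baseline_hazard)

    def enrollment_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (dates, probabilities) of the exposed enrollment draw."""
        if self.enrollment_dates is not None:
            dates, p = self.enrollment_dates
            return np.array(dates, dtype="datetime64[D]"), np.asarray(p, float)
        days = np.arange(
            np.datetime64(self.enrollment_start, "D"),
            np.datetime64(self.enrollment_end, "D") + 1,
        )
        return days, np.full(len(days), 1.0 / len(days))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_log_hr"] = {k: (dict(v) if isinstance(v, Mapping) else float(v))
                            for k, v in self.true_log_hr.items()}
        d["baseline_hazard"] = {k: float(v) for k, v in self.baseline_hazard.items()}
        if isinstance(self.death_log_hr, Mapping):
            d["death_log_hr"] = dict(self.death_log_hr)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        for key in ("care_setting_probs", "n_noise_codes_per_domain",
                    "confounder_effect_on_exposure", "confounder_effect_on_hazard"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("enrollment_dates") is not None:
            dates, p = d["enrollment_dates"]
            d["enrollment_dates"] = (list(dates), list(p))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class CohortSpec:
    """Cohort-construction rules: landmark, lookback, follow-up bounds."""

    landmark_days: int = 30
    lookback_days: int = 365
    historical_offset_days: int = HISTORICAL_OFFSET_DAYS
    #: group -> administrative end of follow-up
    end_of_followup: Mapping[str, str] = field(
        default_factory=lambda: {
            "exposed": END_OF_FOLLOWUP,
            "contemporary": END_OF_FOLLOWUP,
            "historical": "2019-10-31",
        }
    )
    #: whether an outcome event inside (T0, T0+landmark] makes the person
    #: non-incident at the origin ("exclude", default) or is ignored ("retain")
    acute_window: str = "exclude"

    def __post_init__(self) -> None:
        for name in ("landmark_days", "lookback_days", "historical_offset_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.acute_window not in ("exclude", "retain"):
            raise ValueError("acute_window must be 'exclude' or 'retain'")

    def end_for(self, group: str) -> pd.Timestamp:
        return _as_date(self.end_of_followup[group])


@dataclass
class RunConfig:
    """One end-to-end pipeline run (a primary analysis or a sensitivity variant)."""

    comparison: str = "contemporary"  # or "historical"
    outcomes: Sequence[str] | None = None  # None -> all simulated outcomes
    care_setting_stratified: bool = False
    k_highdim: int = 100  # 0 -> predefined covariates only
    min_count: int = 100
    rr_ranking: str = "abs_log"  # or "raw"
    doubly_robust: bool = False
    vaccination_handling: str = "none"  # none | censor | time_varying
    control_t0: str = "latent"  # latent | resample
    weight_truncation_pct: float | None = None
    run_did: bool = False
    did_ci: str = "analytic"  # or "bootstrap" (person-level, honors pre/post overlap)
    burden_resamples: int = 500
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.comparison not in ("contemporary", "historical"):
            raise ValueError("comparison must be 'contemporary' or 'historical'")
        if self.k_highdim < 0:
            raise ValueError("k_highdim must be >= 0")
        if self.vaccination_handling not in ("none", "censor", "time_varying"):
            raise ValueError("bad vaccination_handling")
        if self.control_t0 not in ("latent", "resample"):
            raise ValueError("control_t0 must be 'latent' or 'resample'")
        if self.rr_ranking not in ("abs_log", "raw"):
            raise ValueError("rr_ranking must be 'abs_log' or 'raw'")
        if self.did_ci not in ("analytic", "bootstrap"):
            raise ValueError("did_ci must be 'analytic' or 'bootstrap'")


def config_hash(obj) -> str:
    """Stable hash of a config-like object for run manifests."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
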