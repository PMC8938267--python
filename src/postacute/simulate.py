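"""Seeded synthetic EHR cohort generator with known ground-truth effects.

The generator emulates the statistical structure a target-trial emulation over
claims/EHR data assumes, standing in for the (non-public) source records:

* three exposure groups with distinct enrollment-date distributions
  (contemporary calendar window, and a historical window shifted 730 d back);
* latent confounder factors that shift both group membership and every
  cause-specific log hazard, surfacing as ordinary observed covariates
  (age, smoking, utilization counts, area deprivation, BMI);
* pre-defined continuous/categorical covariates with MCAR missingness;
* hundreds of sparse binary codes across diagnosis/medication/laboratory
  domains, a fraction of them confounder-linked;
* cause-specific exponential event times for multiple outcomes with death as
  a competing risk, with care-setting graded exposure effects;
* vaccination dates for censoring / time-varying-covariate analyses.

Event law: for each outcome the person has a single first-event process whose
hazard clock starts ``clock_back_days`` before the enrollment anchor; the
hazard is ``h0*exp(lp)`` before T0 and ``h0*exp(lp + beta)`` after T0 for the
exposed.  With the default ``clock_back_days`` equal to the history lookback,
all pre-T0 events are visible to (and removed by) the history exclusion, so
post-origin event times in the analysis cohort are exactly exponential.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CARE_SETTINGS, CODE_DOMAINS, SimConfig

_COMORBIDITIES = {
    "cancer": 0.10,
    "ckd": 0.12,
    "chronic_lung_disease": 0.12,
    "dementia": 0.04,
    "diabetes": 0.25,
    "dysautonomia": 0.01,
    "hyperlipidemia": 0.45,
    "hypertension": 0.55,
}

#: covariates carrying the configured confounder effects, in order
CONFOUNDER_ORDER = ("age", "smoking", "utilization", "adi", "bmi")

#: standardization constants for the hazard linear predictor (fixed, not
#: estimated, so configured coefficients have a stable meaning)
_STD = {"age": (62.0, 10.0), "adi": (50.0, 12.0), "bmi": (30.0, 4.5),
        "log1p_outpatient": (1.45, 0.55)}

MISSINGNESS_COLUMNS = ("bmi", "egfr", "sbp", "dbp")


@dataclass
class CohortTables:
    """The generator's output: persons, long-format events, long-format codes."""

    persons: pd.DataFrame
    events: pd.DataFrame
    codes: pd.DataFrame
    config: SimConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.persons.to_csv(out / "persons.csv", index=False)
        self.events.to_csv(out / "events.csv", index=False)
        self.codes.to_csv(out / "codes.csv", index=False)
        self.config.to_yaml(out / "sim_config.yaml")

    @classmethod
    def read(cls, in_dir) -> "CohortTables":
        p = Path(in_dir)
        date_cols = ["t0", "anchor", "death_date", "vaccination_date", "flu_vaccine_date"]
        persons = pd.read_csv(p / "persons.csv", parse_dates=date_cols)
        events = pd.read_csv(p / "events.csv", parse_dates=["event_date"])
        codes = pd.read_csv(p / "codes.csv", parse_dates=["date"])
        return cls(persons, events, codes, SimConfig.from_yaml(p / "sim_config.yaml"))


def _hazard_linear_predictor(cfg: SimConfig, cov: dict[str, np.ndarray]) -> np.ndarray:
    g = np.zeros(5)
    eff = np.asarray(cfg.confounder_effect_on_hazard, float)
    g[: min(5, len(eff))] = eff[:5]
    m, s = _STD["age"]
    lp = g[0] * (cov["age"] - m) / s
    lp += g[1] * (1.0 * (cov["smoking"] == "current") + 0.4 * (cov["smoking"] == "former"))
    m, s = _STD["log1p_outpatient"]
    lp += g[2] * (np.log1p(cov["outpatient_count"]) - m) / s
    m, s = _STD["adi"]
    lp += g[3] * (cov["adi"] - m) / s
    m, s = _STD["bmi"]
    lp += g[4] * (cov["bmi"] - m) / s
    return lp


def _exposure_beta(cfg: SimConfig, beta_spec, exposed: np.ndarray,
                   care_setting: np.ndarray) -> np.ndarray:
    """Per-person post-T0 log hazard ratio (0 for controls)."""
    beta = np.zeros(len(exposed))
    if isinstance(beta_spec, dict):
        for setting, b in beta_spec.items():
            beta[np.asarray(exposed) & (care_setting == setting)] = float(b)
    else:
        beta[np.asarray(exposed)] = float(beta_spec)
    return beta


def _piecewise_event_time(rng, h_pre, h_post, back_days):
    """First-event time (days from clock start) under a two-piece constant hazard."""
    e = rng.exponential(size=len(h_pre))
    cum_pre = h_pre * back_days
    with np.errstate(divide="ignore", invalid="ignore"):
        t_pre = np.where(h_pre > 0, e / np.where(h_pre > 0, h_pre, 1.0), np.inf)
        t_post = back_days + np.where(
            h_post > 0, (e - cum_pre) / np.where(h_post > 0, h_post, 1.0), np.inf
        )
    return np.where(e < cum_pre, t_pre, t_post)


def _offset_dates(clock_start, t_days):
    """clock_start + floor(t) days; infinite times become NaT."""
    finite = np.isfinite(t_days)
    out = np.full(len(t_days), np.datetime64("NaT"), dtype="datetime64[D]")
    out[finite] = (clock_start[finite]
                   + np.floor(t_days[finite]).astype("timedelta64[D]"))
    return out


def generate_cohort(config: SimConfig) -> CohortTables:
    """Generate a seeded synthetic cohort; identical config+seed => identical output."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    (s_anchor, s_cov, s_event, s_codes, s_vax) = [
        np.random.default_rng(c) for c in ss.spawn(5)
    ]

    n = cfg.n_exposed + cfg.n_contemporary + cfg.n_historical
    group = np.repeat(
        np.array(["exposed", "contemporary", "historical"]),
        [cfg.n_exposed, cfg.n_contemporary, cfg.n_historical],
    )
    exposed = group == "exposed"
    person_id = np.array([f"P{i:07d}" for i in range(n)])

    # --- enrollment anchors -------------------------------------------------
    dates, probs = cfg.enrollment_distribution()
    anchor = dates[s_anchor.choice(len(dates), size=n, p=probs)]
    from .config import HISTORICAL_OFFSET_DAYS

    anchor[group == "historical"] -= np.timedelta64(HISTORICAL_OFFSET_DAYS, "D")
    anchor = anchor.astype("datetime64[D]")

    care_setting = np.full(n, "none", dtype=object)
    cs_idx = s_cov.choice(3, size=int(exposed.sum()), p=np.asarray(cfg.care_setting_probs))
    care_setting[exposed] = np.array(CARE_SETTINGS, dtype=object)[cs_idx]

    # --- confounders and covariates -----------------------------------------
    delta = np.zeros(5)
    de = np.asarray(cfg.confounder_effect_on_exposure, float)
    delta[: min(5, len(de))] = de[:5]
    z = s_cov.normal(size=(n, 5))
    z[exposed] += delta  # mean shift induces exposure-covariate association

    cov: dict[str, np.ndarray] = {}
    cov["age"] = np.clip(62.0 + 10.0 * z[:, 0], 20.0, 105.0)
    # ordered thresholds on the latent factor give group-dependent categories
    cov["smoking"] = np.where(z[:, 1] > 0.9, "current",
                              np.where(z[:, 1] > 0.1, "former", "never")).astype(object)
    cov["outpatient_count"] = s_cov.poisson(np.exp(1.2 + 0.45 * z[:, 2]))
    cov["inpatient_count"] = s_cov.poisson(np.exp(-1.6 + 0.5 * z[:, 2]))
    cov["long_term_care"] = (
        s_cov.random(n) < 1.0 / (1.0 + np.exp(-(-3.0 + 0.7 * z[:, 2])))
    ).astype(int)
    cov["adi"] = np.clip(50.0 + 12.0 * z[:, 3], 1.0, 100.0)
    cov["bmi"] = np.clip(30.0 + 4.5 * z[:, 4] + 0.8 * z[:, 0], 15.0, 60.0)
    # noise covariates: associated with exposure or age only, no hazard effect
    cov["sex"] = np.where(s_cov.random(n) < 0.88, "male", "female").astype(object)
    p_black = np.where(exposed, 0.22, 0.18)
    u = s_cov.random(n)
    cov["race"] = np.where(u < p_black, "black",
                           np.where(u < p_black + 0.10, "other", "white")).astype(object)
    w = s_cov.normal(size=(n, 3))
    cov["egfr"] = np.clip(78.0 - 6.0 * z[:, 0] - 10.0 * w[:, 0], 5.0, 150.0)
    cov["sbp"] = 132.0 + 4.0 * z[:, 0] + 14.0 * w[:, 1]
    cov["dbp"] = 78.0 + 10.0 * w[:, 2]
    for name, p0 in _COMORBIDITIES.items():
        logit = np.log(p0 / (1 - p0)) + 0.5 * (cov["age"] - 62.0) / 10.0
        cov[name] = (s_cov.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    lp = _hazard_linear_predictor(cfg, cov)

    # --- event and death dates ----------------------------------------------
    back = cfg.clock_back_days
    clock_start = anchor - np.timedelta64(back, "D")
    end_exposed = np.datetime64(cfg.admin_censor_date, "D")
    group_end = np.where(group == "historical",
                         end_exposed - np.timedelta64(HISTORICAL_OFFSET_DAYS, "D"),
                         end_exposed)

    beta_death = _exposure_beta(cfg, cfg.death_log_hr, exposed, care_setting)
    h_pre = cfg.death_hazard * np.exp(lp)
    t_death = _piecewise_event_time(s_event, h_pre, h_pre * np.exp(beta_death), back)
    death_date = _offset_dates(clock_start, t_death)
    death_date = np.where(death_date <= group_end, death_date, np.datetime64("NaT"))

    event_rows = []
    for outcome in cfg.outcomes:
        beta = _exposure_beta(cfg, cfg.true_log_hr.get(outcome, 0.0), exposed, care_setting)
        h0 = cfg.baseline_hazard[outcome]
        h_pre = h0 * np.exp(lp)
        t = _piecewise_event_time(s_event, h_pre, h_pre * np.exp(beta), back)
        date = _offset_dates(clock_start, t)
        ok = (date <= group_end) & ~(
            (~pd.isna(death_date)) & (date > death_date)
        )
        idx = np.flatnonzero(ok)
        event_rows.append(pd.DataFrame({
            "person_id": person_id[idx],
            "outcome": outcome,
            "event_date": pd.to_datetime(date[idx]).astype("datetime64[ns]"),
        }))
    events = (pd.concat(event_rows, ignore_index=True)
              if event_rows else
              pd.DataFrame(columns=["person_id", "outcome", "event_date"]))

    # --- vaccination --------------------------------------------------------
    contemporary_era = group != "historical"
    vax_start = np.datetime64("2020-12-11", "D")
    span = int((end_exposed - vax_start).astype(int))
    vax_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    pick = contemporary_era & (s_vax.random(n) < cfg.vaccination_rate)
    vax_date[pick] = vax_start + s_vax.integers(0, span + 1, size=int(pick.sum())).astype(
        "timedelta64[D]")
    flu_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    pick = contemporary_era & (s_vax.random(n) < cfg.flu_vaccination_rate)
    enroll_days, enroll_p = cfg.enrollment_distribution()
    flu_date[pick] = enroll_days[
        s_vax.choice(len(enroll_days), size=int(pick.sum()), p=enroll_p)
    ]

    # --- high-dimensional codes ---------------------------------------------
    code_rows = []
    for d_i, domain in enumerate(CODE_DOMAINS):
        k = int(cfg.n_noise_codes_per_domain[d_i])
        if k == 0:
            continue
        base_prev = 10 ** s_codes.uniform(np.log10(0.002), np.log10(0.15), size=k)
        n_linked = max(1, k // 5)
        slope = np.zeros(k)
        slope[:n_linked] = s_codes.uniform(-0.5, 0.5, size=n_linked)
        age_std = (cov["age"] - 62.0) / 10.0
        for start in range(0, k, 64):
            blk = slice(start, min(start + 64, k))
            logit = (np.log(base_prev[blk] / (1 - base_prev[blk]))[None, :]
                     + slope[blk][None, :] * age_std[:, None])
            occ = s_codes.random((n, logit.shape[1])) < 1.0 / (1.0 + np.exp(-logit))
            pi, ci = np.nonzero(occ)
            offs = s_codes.integers(1, 366, size=len(pi))
            code_rows.append(pd.DataFrame({
                "person_id": person_id[pi],
                "domain": domain,
                "code": np.array([f"{domain[:3]}_{start + c:04d}" for c in ci]),
                "date": pd.to_datetime(anchor[pi] - offs.astype("timedelta64[D]")).astype("datetime64[ns]"),
            }))
    codes = (pd.concat(code_rows, ignore_index=True)
             if code_rows else
             pd.DataFrame(columns=["person_id", "domain", "code", "date"]))

    def _dt(x):
        return pd.to_datetime(x).astype("datetime64[ns]")

    persons = pd.DataFrame({
        "person_id": person_id,
        "group": group,
        "care_setting": care_setting,
        "t0": _dt(np.where(exposed, anchor, np.datetime64("NaT"))),
        "anchor": _dt(anchor),
        "death_date": _dt(death_date),
        "vaccination_date": _dt(vax_date),
        "flu_vaccine_date": _dt(flu_date),
        **{k: v for k, v in cov.items()},
    })

    # MCAR missingness on lab/vital covariates (observed table only; hazards
    # above already used the true values)
    miss_rng = np.random.default_rng(ss.spawn(1)[0])
    for col in MISSINGNESS_COLUMNS:
        mask = miss_rng.random(n) < cfg.missing_rate
        persons.loc[mask, col] = np.nan

    return CohortTables(persons, events, codes, cfg)


def inject_history(tables: CohortTables, outcome: str, fraction: float,
                   seed: int, lookback_days: int = 365) -> CohortTables:
    """Give an exact ``floor(fraction*n)``-sized random subset of persons a
    first occurrence of ``outcome`` inside the pre-anchor lookback window.

    Testing utility for the history-exclusion logic; overwrites any existing
    first occurrence for the chosen persons.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if outcome not in tables.config.outcomes:
        raise KeyError(f"unknown outcome {outcome!r}")
    if fraction == 0:
        return tables
    rng = np.random.default_rng(seed)
    persons = tables.persons
    n_flag = int(np.floor(fraction * len(persons)))
    chosen = rng.choice(len(persons), size=n_flag, replace=False)
    offsets = rng.integers(1, lookback_days + 1, size=n_flag)
    new_dates = (persons["anchor"].to_numpy("datetime64[D]")[chosen]
                 - offsets.astype("timedelta64[D]"))
    chosen_ids = persons["person_id"].to_numpy()[chosen]

    events = tables.events
    keep = ~((events["outcome"] == outcome) & events["person_id"].isin(chosen_ids))
    injected = pd.DataFrame({
        "person_id": chosen_ids,
        "outcome": outcome,
        "event_date": pd.to_datetime(new_dates).astype("datetime64[ns]"),
    })
    new_events = pd.concat([events[keep], injected], ignore_index=True)
    return CohortTables(persons, new_events, tables.codes, tables.config)
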