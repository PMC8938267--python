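"""Replicate-based validation experiments over the synthetic cohort.

These are the package's "does the pipeline recover known truth" studies:
parameter recovery under confounding, confidence-interval coverage, the
closed-form competing-risk burden check, covariate balance, the graded
care-setting severity ordering, and the control batteries.  Problem sizes
are the package's validation study conditions; each function is deterministic
given its seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import build_subcohort
from .config import CohortSpec, RunConfig, SimConfig
from .controls import ControlSpec, run_battery
from .pipeline import analyze_outcome, prepare_persons, run_pipeline
from .simulate import generate_cohort
from .survival import aalen_johansen, fit_weighted_cox

TRUE_HR_EFFECT = 1.7
TRUE_HR_NULL = 1.0


def _child_seeds(seed: int, n: int) -> list[int]:
    # keep spawned seeds below 2**31 for portability of configs
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31 - 1)]


def recovery_config(seed: int, n_per_group: int, clock_back_days: int = 365,
                    with_codes: bool = False) -> SimConfig:
    """Confounded two-outcome world: one true effect (HR 1.7), one null,
    with an active death hazard.  Confounder effects are the generator
    defaults."""
    return SimConfig(
        n_exposed=n_per_group, n_contemporary=n_per_group, n_historical=1,
        n_noise_codes_per_domain=(30, 30, 10) if with_codes else (0, 0, 0),
        true_log_hr={"effect_outcome": float(np.log(TRUE_HR_EFFECT)),
                     "null_outcome": 0.0},
        baseline_hazard={"effect_outcome": 1.5e-4, "null_outcome": 1.5e-4},
        clock_back_days=clock_back_days,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Parameter recovery: weighting corrects confounding, crude does not
# --------------------------------------------------------------------------

def parameter_recovery(seed: int = 0, n_per_group: int = 50_000,
                       replicates: int = 25) -> dict:
    spec = CohortSpec()
    rows = []
    for rep_seed in _child_seeds(seed, replicates):
        tables = generate_cohort(recovery_config(rep_seed, n_per_group))
        run_cfg = RunConfig(k_highdim=0, seed=rep_seed)
        prepared = prepare_persons(tables, run_cfg, spec)
        for outcome, truth in (("effect_outcome", np.log(TRUE_HR_EFFECT)),
                               ("null_outcome", 0.0)):
            res, _ = analyze_outcome(tables, outcome, run_cfg, spec,
                                     prepared=prepared, compute_burden=False)
            sub = build_subcohort(prepared, tables.events, outcome, spec)
            crude = fit_weighted_cox(sub.data, None, outcome=outcome)
            rows.append({
                "outcome": outcome,
                "weighted_bias": np.log(res[0].hazard.hr) - truth,
                "crude_bias": np.log(crude.hr) - truth,
            })
    df = pd.DataFrame(rows)
    agg = df.groupby("outcome").mean()
    return {
        "weighted_bias_effect": float(agg.loc["effect_outcome", "weighted_bias"]),
        "weighted_bias_null": float(agg.loc["null_outcome", "weighted_bias"]),
        "crude_bias_effect": float(agg.loc["effect_outcome", "crude_bias"]),
        "crude_bias_null": float(agg.loc["null_outcome", "crude_bias"]),
        "replicates": replicates, "n_per_group": n_per_group,
    }


# --------------------------------------------------------------------------
# CI coverage: weighted Cox HR and DiD ratio of IRRs
# --------------------------------------------------------------------------

def ci_coverage(seed: int = 0, n_per_group: int = 5_000,
                replicates: int = 200, did_resamples: int = 200) -> dict:
    spec = CohortSpec()
    truth = TRUE_HR_EFFECT
    cox_cover, did_cover = [], []
    for rep_seed in _child_seeds(seed, replicates):
        tables = generate_cohort(
            recovery_config(rep_seed, n_per_group, clock_back_days=1100))
        run_cfg = RunConfig(k_highdim=0, run_did=True, did_ci="bootstrap",
                            burden_resamples=did_resamples, seed=rep_seed)
        res, _ = analyze_outcome(tables, "effect_outcome", run_cfg, spec,
                                 compute_burden=False)
        lo, hi = res[0].hazard.ci95
        cox_cover.append(lo <= truth <= hi)
        lo, hi = res[0].did.ratio_ci95
        did_cover.append(lo <= truth <= hi)
    return {
        "cox_ci_coverage": float(np.mean(cox_cover)),
        "did_ci_coverage": float(np.mean(did_cover)),
        "replicates": replicates, "n_per_group": n_per_group,
    }


# --------------------------------------------------------------------------
# Closed-form competing-risk burden oracle
# --------------------------------------------------------------------------

def burden_closed_form(seed: int = 0, n: int = 100_000,
                       h_outcome: float = 3.0e-4, h_death: float = 2.0e-4) -> dict:
    """Constant competing hazards: CIF(365) must equal
    h1/(h1+h2) * (1 - exp(-(h1+h2)*365)) within binomial error."""
    cfg = SimConfig(
        n_exposed=n, n_contemporary=1, n_historical=1,
        enrollment_dates=(["2020-06-01"], [1.0]),
        n_noise_codes_per_domain=(0, 0, 0),
        true_log_hr={"outcome": 0.0},
        baseline_hazard={"outcome": h_outcome},
        death_hazard=h_death, death_log_hr=0.0,
        confounder_effect_on_exposure=(0,) * 5,
        confounder_effect_on_hazard=(0,) * 5,
        vaccination_rate=0.0, flu_vaccination_rate=0.0,
        seed=seed,
    )
    tables = generate_cohort(cfg)
    spec = CohortSpec()
    prepared = prepare_persons(tables, RunConfig(k_highdim=0, seed=seed), spec)
    sub = build_subcohort(prepared, tables.events, "outcome", spec).data
    est = aalen_johansen(sub["time"], sub["event"], sub["death"],
                         horizon_days=365.0)
    h = h_outcome + h_death
    theory = h_outcome / h * (1.0 - np.exp(-h * 365.0))
    se = np.sqrt(theory * (1 - theory) / len(sub))
    return {
        "cif_estimate_per_1000": 1000.0 * float(est),
        "cif_theory_per_1000": 1000.0 * float(theory),
        "cif_z": float((est - theory) / se),
        "n": int(len(sub)),
    }


# --------------------------------------------------------------------------
# Balance after weighting
# --------------------------------------------------------------------------

def balance_after_weighting(seed: int = 0, n_per_group: int = 10_000) -> dict:
    tables = generate_cohort(recovery_config(seed, n_per_group, with_codes=True))
    run_cfg = RunConfig(k_highdim=20, min_count=50, seed=seed)
    _, diag = analyze_outcome(tables, "effect_outcome", run_cfg,
                              compute_burden=False)
    bal = diag["balance"]
    return {
        "max_smd_before": float(bal.table["smd_before"].abs().max()),
        "max_smd_after": bal.max_abs_smd_after,
        "n_per_group": n_per_group,
        "n_covariates": int(len(bal.table)),
    }


# --------------------------------------------------------------------------
# Graded severity ordering
# --------------------------------------------------------------------------

GRADED_HRS = {"non_hospitalized": 1.2, "hospitalized": 1.8, "icu": 2.5}


def graded_severity(seed: int = 0, n_per_group: int = 20_000,
                    replicates: int = 50) -> dict:
    spec = CohortSpec()
    ordered = []
    for rep_seed in _child_seeds(seed, replicates):
        cfg = SimConfig(
            n_exposed=n_per_group, n_contemporary=n_per_group, n_historical=1,
            n_noise_codes_per_domain=(0, 0, 0),
            true_log_hr={"outcome": {k: float(np.log(v))
                                     for k, v in GRADED_HRS.items()}},
            baseline_hazard={"outcome": 2.0e-4},
            seed=rep_seed,
        )
        tables = generate_cohort(cfg)
        run_cfg = RunConfig(k_highdim=0, care_setting_stratified=True,
                            seed=rep_seed)
        res, _ = analyze_outcome(tables, "outcome", run_cfg, spec,
                                 compute_burden=False)
        hrs = {r.care_setting: r.hazard.hr for r in res if r.care_setting != "all"}
        ordered.append(hrs["non_hospitalized"] < hrs["hospitalized"] < hrs["icu"])
    return {"ordering_rate": float(np.mean(ordered)),
            "replicates": replicates, "n_per_group": n_per_group}


# --------------------------------------------------------------------------
# Control batteries
# --------------------------------------------------------------------------

def negative_outcome_coverage(seed: int = 0, n_per_group: int = 6_000,
                              replicates: int = 25, n_outcomes: int = 4) -> dict:
    """Null outcomes re-analyzed through the identical pipeline: per-control
    CIs should cover 1 at about the nominal rate."""
    spec = CohortSpec()
    covered = []
    names = [f"neg_{i}" for i in range(n_outcomes)]
    for rep_seed in _child_seeds(seed, replicates):
        cfg = SimConfig(
            n_exposed=n_per_group, n_contemporary=n_per_group, n_historical=1,
            n_noise_codes_per_domain=(0, 0, 0),
            true_log_hr={o: 0.0 for o in names},
            baseline_hazard={o: 2.0e-4 for o in names},
            seed=rep_seed,
        )
        tables = generate_cohort(cfg)
        specs = [ControlSpec("negative_outcome", f"neg:{o}", "nonsignificant",
                             outcome=o) for o in names]
        report = run_battery(specs, tables, RunConfig(k_highdim=0, seed=rep_seed),
                             spec)
        covered.extend(report["met"].tolist())
    return {"negative_control_coverage": float(np.mean(covered)),
            "n_controls": len(covered), "n_per_group": n_per_group}


def positive_and_parity_controls(seed: int = 0, n_per_group: int = 20_000) -> dict:
    """One large null world with a built-in positive control (true HR 1.5):
    the positive control must be detected and the influenza-parity
    negative-exposure split must show no association for any outcome."""
    cfg = SimConfig(
        n_exposed=n_per_group, n_contemporary=n_per_group, n_historical=1,
        n_noise_codes_per_domain=(0, 0, 0),
        true_log_hr={"positive_control": float(np.log(1.5)),
                     "null_a": 0.0, "null_b": 0.0, "null_c": 0.0},
        baseline_hazard={"positive_control": 3.0e-4, "null_a": 2.0e-4,
                         "null_b": 2.0e-4, "null_c": 2.0e-4},
        seed=seed,
    )
    tables = generate_cohort(cfg)
    specs = [
        ControlSpec("positive_outcome", "pos:positive_control",
                    "significant_gt1", outcome="positive_control"),
        ControlSpec("negative_exposure", "flu-parity", "nonsignificant"),
    ]
    report = run_battery(specs, tables, RunConfig(k_highdim=0, seed=seed),
                         outcomes_for_exposure_controls=["null_a", "null_b",
                                                         "null_c"])
    pos = report[report["kind"] == "positive_outcome"]
    par = report[report["kind"] == "negative_exposure"]
    return {
        "positive_control_hr": float(pos["hr"].iloc[0]),
        "positive_control_detected": bool(pos["met"].all()),
        "parity_n_significant": int((~par["met"]).sum()),
        "parity_n_outcomes": int(len(par)),
        "n_per_group": n_per_group,
    }


# --------------------------------------------------------------------------
# Determinism
# --------------------------------------------------------------------------

def determinism_check(seed: int = 0, n_per_group: int = 2_000) -> dict:
    import tempfile
    from pathlib import Path

    def one(out_dir: str) -> bytes:
        cfg = recovery_config(seed, n_per_group, with_codes=True)
        tables = generate_cohort(cfg)
        run_pipeline(tables, RunConfig(k_highdim=10, min_count=20, seed=seed,
                                       burden_resamples=100,
                                       output_dir=out_dir))
        return b"".join(sorted(
            p.read_bytes() for p in Path(out_dir).glob("*.csv")))

    with tempfile.TemporaryDirectory() as d1, \
            tempfile.TemporaryDirectory() as d2:
        identical = one(d1) == one(d2)
    return {"byte_identical": bool(identical), "n_per_group": n_per_group}
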