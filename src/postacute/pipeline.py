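"""End-to-end orchestration: cohort build -> covariate selection -> weighting
-> survival estimation -> (difference-in-differences), with a run manifest.

Every stage seeds its randomness from the run seed, so identical
configuration + seed reproduce byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import apply_landmark, assign_control_t0, build_subcohort
from .config import CohortSpec, RunConfig, SimConfig, config_hash
from .covariates import build_design_matrix, rank_high_dim
from .did import build_pre_period, did_ratio, did_ratio_bootstrap, incident_rate_ratio
from .simulate import CohortTables
from .survival import censor_at, excess_burden, fit_time_varying, fit_weighted_cox
from .weighting import (balance_report, fit_group_membership,
                        mixture_target_weights)


@dataclass
class OutcomeResult:
    """Everything estimated for one outcome in one comparison."""

    outcome: str
    comparison: str
    care_setting: str  # "all" or a stratum
    hazard: object
    burden: object | None = None
    did: object | None = None


@dataclass
class PipelineResult:
    results: list[OutcomeResult]
    balance: dict
    selections: dict
    manifest: dict

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"care_setting": r.care_setting, **r.hazard.to_dict()}
            if r.burden is not None:
                row.update(r.burden.to_dict())
            if r.did is not None:
                row.update({f"did_{k}": v for k, v in r.did.to_dict().items()
                            if k not in ("outcome", "comparison")})
            rows.append(row)
        return pd.DataFrame(rows)


def default_composites(config: SimConfig) -> dict:
    """Composite outcomes expressible in the simulated world."""
    comps = {}
    have = set(config.outcomes)
    if {"stroke", "mi"} <= have:
        comps["mace"] = (["stroke", "mi", "death"], True)
    if len(have) > 1:
        comps["any_outcome"] = (sorted(have), False)
    return comps


def prepare_persons(tables: CohortTables, run_cfg: RunConfig,
                    spec: CohortSpec) -> pd.DataFrame:
    """Assign control T0, apply the landmark filter; keeps the exposed group,
    the comparison group, and the contemporary group (target sample)."""
    groups = {"exposed", "contemporary", run_cfg.comparison}
    persons = tables.persons[tables.persons["group"].isin(groups)].copy()
    if run_cfg.control_t0 == "latent":
        persons.loc[persons["t0"].isna(), "t0"] = persons.loc[
            persons["t0"].isna(), "anchor"]
    else:
        exposed_t0 = persons.loc[persons["group"] == "exposed", "t0"]
        for g, offset in (("contemporary", 0), ("historical",
                                                spec.historical_offset_days)):
            ids = persons.index[persons["group"] == g]
            if len(ids) == 0:
                continue
            t0 = assign_control_t0(exposed_t0, ids, offset_days=offset,
                                   seed=run_cfg.seed + (1 if offset == 0 else 2))
            persons.loc[ids, "t0"] = t0
    return apply_landmark(persons, spec)


def _design_for(persons: pd.DataFrame, tables: CohortTables, run_cfg: RunConfig,
                exposure_labels: pd.Series | None):
    """Design matrix for the given persons; optionally with high-dimensional
    selection against the supplied exposure labels."""
    selection = None
    if run_cfg.k_highdim > 0 and exposure_labels is not None:
        selection = rank_high_dim(tables.codes, exposure_labels,
                                  min_count=run_cfg.min_count,
                                  k=run_cfg.k_highdim,
                                  ranking=run_cfg.rr_ranking)
    X, meta = build_design_matrix(persons, codes=tables.codes, selection=selection)
    return X, meta, selection


def analyze_outcome(tables: CohortTables, outcome: str, run_cfg: RunConfig,
                    spec: CohortSpec | None = None,
                    prepared: pd.DataFrame | None = None,
                    components: list[str] | None = None,
                    death_is_event: bool = False,
                    compute_burden: bool = True) -> tuple[list[OutcomeResult], dict]:
    """Full analysis of one outcome: subcohort, selection, weights, HR,
    burden, and optionally care-setting strata and DiD."""
    spec = spec or CohortSpec()
    persons = prepared if prepared is not None else prepare_persons(tables, run_cfg, spec)
    sub = build_subcohort(persons, tables.events, outcome, spec,
                          components=components, death_is_event=death_is_event)
    data = sub.data
    comparison_groups = ("exposed", run_cfg.comparison)
    comp_mask = data["group"].isin(comparison_groups).to_numpy()

    idx = persons.set_index("person_id")
    sub_persons = idx.loc[data["person_id"]].reset_index()
    exposure_labels = pd.Series(
        (data.loc[comp_mask, "group"] == "exposed").to_numpy(),
        index=data.loc[comp_mask, "person_id"])
    X, meta, selection = _design_for(sub_persons, tables, run_cfg, exposure_labels)
    X = X.reset_index(drop=True)

    results: list[OutcomeResult] = []
    diagnostics: dict = {"selection": selection, "n_subcohort": len(data)}

    # one well-specified group-membership model serves the whole outcome:
    # exposed persons are labelled by care setting when strata are requested,
    # so each stratum is standardized by its own density
    if run_cfg.care_setting_stratified:
        classes = np.where(data["group"] == "exposed",
                           "exposed_" + data["care_setting"].astype(str),
                           data["group"])
    else:
        classes = data["group"].to_numpy()
    membership = fit_group_membership(X, classes)
    exposed_classes = [c for c in membership.columns
                       if str(c).startswith("exposed")]
    target_groups = exposed_classes + ["contemporary"]
    # main analysis: the exposed arm pools its care-setting classes
    weights_main = mixture_target_weights(
        membership, data["group"], target_groups,
        run_cfg.weight_truncation_pct, arm_classes={"exposed": exposed_classes})
    # stratified analyses: each care-setting stratum is its own arm
    weights_strata = (mixture_target_weights(membership, classes, target_groups,
                                             run_cfg.weight_truncation_pct)
                      if run_cfg.care_setting_stratified else weights_main)

    def estimate(arm_rows, arm_data, arm_X, setting, weight_pool):
        w = weight_pool[arm_rows]
        est_data, est_w, est_X = arm_data, w, arm_X
        if run_cfg.vaccination_handling == "censor":
            vax = tables.persons.set_index("person_id")["vaccination_date"]
            est_data, _ = censor_at(arm_data.assign(_w=w, _row=np.arange(len(arm_data))), vax)
            est_w = est_data.pop("_w").to_numpy()
            est_X = arm_X.iloc[est_data.pop("_row").to_numpy()]
        if run_cfg.vaccination_handling == "time_varying":
            vax = tables.persons.set_index("person_id")["vaccination_date"]
            hr = fit_time_varying(est_data, est_w, vax, outcome=outcome,
                                  comparison=run_cfg.comparison)
        else:
            cov = est_X if run_cfg.doubly_robust else None
            hr = fit_weighted_cox(est_data, est_w, covariates=cov,
                                  outcome=outcome, comparison=run_cfg.comparison)
        burden = None
        if compute_burden and run_cfg.vaccination_handling != "time_varying":
            burden = excess_burden(est_data, est_w, horizon_days=365.0,
                                   resamples=run_cfg.burden_resamples,
                                   seed=run_cfg.seed + 17, outcome=outcome)
        res = OutcomeResult(outcome=outcome, comparison=run_cfg.comparison,
                            care_setting=setting, hazard=hr, burden=burden)
        return res, w

    comp_rows = np.flatnonzero(comp_mask)
    comp_data = data[comp_mask].reset_index(drop=True)
    comp_X = X[comp_mask].reset_index(drop=True)
    g_main = (comp_data["group"] == "exposed").to_numpy()
    main, w_main = estimate(comp_rows, comp_data, comp_X, "all", weights_main)

    if run_cfg.run_did:
        post_days = pd.Series(comp_data["time"].to_numpy(),
                              index=comp_data["person_id"])
        pre_all, n_hist = build_pre_period(persons, tables.events, outcome,
                                           post_days,
                                           lookback_days=spec.lookback_days,
                                           components=components)
        pre_persons = idx.loc[pre_all["person_id"]].reset_index()
        Xpre, _ = build_design_matrix(pre_persons, codes=tables.codes,
                                      selection=selection)
        Xpre = Xpre.reset_index(drop=True)
        memb_pre = fit_group_membership(Xpre, pre_all["group"])
        w_pre_all = mixture_target_weights(
            memb_pre, pre_all["group"],
            [c for c in memb_pre.columns if c in ("exposed", "contemporary")],
            run_cfg.weight_truncation_pct)
        keep = pre_all["group"].isin(comparison_groups).to_numpy()
        pre = pre_all[keep].reset_index(drop=True)
        w_pre = w_pre_all[keep]
        g_pre = (pre["group"] == "exposed").to_numpy()
        post_tab = pd.DataFrame({
            "person_id": comp_data["person_id"], "group": comp_data["group"],
            "events": comp_data["event"], "persontime": comp_data["time"],
        })
        if run_cfg.did_ci == "bootstrap":
            did = did_ratio_bootstrap(pre, post_tab, w_pre, w_main,
                                      resamples=run_cfg.burden_resamples,
                                      seed=run_cfg.seed + 29,
                                      outcome=outcome, comparison=run_cfg.comparison)
        else:
            irr_pre = incident_rate_ratio(pre["events"], pre["persontime"], g_pre, w_pre)
            irr_post = incident_rate_ratio(post_tab["events"], post_tab["persontime"],
                                           g_main, w_main)
            did = did_ratio(irr_pre, irr_post, outcome, run_cfg.comparison)
        main.did = did
        diagnostics["did_pre_history_excluded"] = n_hist
    results.append(main)
    diagnostics["balance"] = balance_report(comp_X, g_main, w_main)
    # per-person weight table: w = p/(1-p) with p the target-membership
    # propensity, so p = w/(1+w)
    diagnostics["weights"] = pd.DataFrame({
        "person_id": comp_data["person_id"],
        "group": comp_data["group"],
        "propensity": w_main / (1.0 + w_main),
        "weight": w_main,
    })

    if run_cfg.care_setting_stratified:
        for setting in ("non_hospitalized", "hospitalized", "icu"):
            smask = ((comp_data["group"] != "exposed")
                     | (comp_data["care_setting"] == setting)).to_numpy()
            sdata = comp_data[smask].reset_index(drop=True)
            sX = comp_X[smask].reset_index(drop=True)
            try:
                res, _ = estimate(comp_rows[smask], sdata, sX, setting,
                                  weights_strata)
            except ValueError as err:
                res = OutcomeResult(outcome, run_cfg.comparison, setting,
                                    hazard=_inestimable(outcome, run_cfg.comparison,
                                                        str(err)))
            results.append(res)
    return results, diagnostics


def _inestimable(outcome, comparison, reason):
    from .survival import HazardResult
    r = HazardResult(outcome=outcome, comparison=comparison, hr=float("nan"),
                     log_hr_se=float("nan"), ci95=(float("nan"), float("nan")),
                     n_exposed=0, n_control=0, events_exposed=0, events_control=0)
    r.reason = reason
    return r


def did_by_care_setting(tables: CohortTables, outcome: str,
                        run_cfg: RunConfig,
                        spec: CohortSpec | None = None) -> pd.DataFrame:
    """Difference-in-differences per mutually exclusive care-setting stratum:
    each stratum's exposed persons against the full control arm."""
    import dataclasses

    spec = spec or CohortSpec()
    cfg = dataclasses.replace(run_cfg, run_did=True,
                              care_setting_stratified=False)
    rows = []
    for setting in ("non_hospitalized", "hospitalized", "icu"):
        keep = ((tables.persons["group"] != "exposed")
                | (tables.persons["care_setting"] == setting))
        subset = CohortTables(tables.persons[keep].reset_index(drop=True),
                              tables.events, tables.codes, tables.config)
        res, _ = analyze_outcome(subset, outcome, cfg, spec,
                                 compute_burden=False)
        rows.append({"care_setting": setting, **res[0].did.to_dict()})
    return pd.DataFrame(rows)


def run_pipeline(tables: CohortTables, run_cfg: RunConfig,
                 spec: CohortSpec | None = None,
                 composites: dict | None = None) -> PipelineResult:
    """Execute the full pipeline for every requested outcome and write tidy
    outputs plus a manifest (and a stage log) when ``run_cfg.output_dir``
    is set."""
    import time as _time

    t_start = _time.perf_counter()
    spec = spec or CohortSpec()
    persons = prepare_persons(tables, run_cfg, spec)
    stage_log = [f"landmark: {len(tables.persons)} -> {len(persons)} persons "
                 f"(excluded {len(tables.persons) - len(persons)})"]
    if composites is None:
        composites = default_composites(tables.config)
    outcomes = list(run_cfg.outcomes or tables.config.outcomes)

    all_results: list[OutcomeResult] = []
    balance, selections, subcohort_sizes = {}, {}, {}
    for outcome in outcomes:
        t_out = _time.perf_counter()
        comp = composites.get(outcome)
        components, death_is_event = (comp if comp else (None, False))
        res, diag = analyze_outcome(tables, outcome, run_cfg, spec,
                                    prepared=persons, components=components,
                                    death_is_event=death_is_event)
        all_results.extend(res)
        balance[outcome] = diag["balance"]
        selections[outcome] = diag["selection"]
        subcohort_sizes[outcome] = diag["n_subcohort"]
        stage_log.append(
            f"{outcome}: subcohort {diag['n_subcohort']} "
            f"(excluded {len(persons) - diag['n_subcohort']}), "
            f"{_time.perf_counter() - t_out:.2f} s")

    cfg_for_hash = {k: v for k, v in vars(run_cfg).items() if k != "output_dir"}
    manifest = {
        "run_config": config_hash(cfg_for_hash),
        "sim_config": config_hash(tables.config.to_dict()),
        "seed": run_cfg.seed,
        "version": __version__,
        "n_persons_landmarked": int(len(persons)),
        "n_subcohort": subcohort_sizes,
        "outcomes": outcomes,
        "selection_skipped": run_cfg.k_highdim == 0,
        "n_selected": {o: (len(s.selected) if s else 0) for o, s in selections.items()},
    }
    result = PipelineResult(all_results, balance, selections, manifest)

    if run_cfg.output_dir:
        out = Path(run_cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.table().to_csv(out / "results.csv", index=False)
        pd.concat({o: b.table for o, b in balance.items()},
                  names=["outcome", None]).reset_index(level=0).to_csv(
            out / "balance.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        stage_log.append(f"total: {_time.perf_counter() - t_start:.2f} s")
        # timings are run-dependent, so they live in the log, not the
        # (byte-reproducible) manifest
        (out / "run.log").write_text("\n".join(stage_log) + "\n")
    return result


def subgroup_analysis(tables: CohortTables, run_cfg: RunConfig,
                      subgroup_defs: dict, outcome: str,
                      spec: CohortSpec | None = None) -> pd.DataFrame:
    """Re-run selection + weighting + estimation within each subgroup.

    ``subgroup_defs`` maps a name to a boolean function of the persons table.
    Subgroups where the model cannot be fitted are reported as inestimable
    rather than dropped."""
    spec = spec or CohortSpec()
    rows = []
    for name, fn in subgroup_defs.items():
        mask = fn(tables.persons)
        subset = CohortTables(tables.persons[mask].reset_index(drop=True),
                              tables.events, tables.codes, tables.config)
        try:
            res, _ = analyze_outcome(subset, outcome, run_cfg, spec,
                                     compute_burden=False)
            rows.append({"subgroup": name, **res[0].hazard.to_dict(),
                         "inestimable": False})
        except ValueError as err:
            rows.append({"subgroup": name, "outcome": outcome,
                         "inestimable": True, "reason": str(err)})
    return pd.DataFrame(rows)
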