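"""Difference-in-differences analysis of incident rate ratios.

Each person contributes a pre-exposure window of exactly the same length as
their post-exposure follow-up, ending at T0.  Incident rate ratios (IRR,
weighted events per weighted person-time, exposed over control) are computed
in each period with weights standardizing both arms to the common target
population on pre-exposure characteristics; the ratio of the post- to
pre-period IRR cancels time-invariant group differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import Z95


@dataclass
class IRRResult:
    irr: float
    log_se: float
    ci95: tuple[float, float]
    events_exposed: float
    events_control: float
    persontime_exposed: float
    persontime_control: float


@dataclass
class DiDResult:
    outcome: str
    comparison: str
    irr_pre: IRRResult
    irr_post: IRRResult
    ratio: float
    ratio_ci95: tuple[float, float]

    @property
    def significant(self) -> bool:
        lo, hi = self.ratio_ci95
        return lo > 1.0 or hi < 1.0

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "comparison": self.comparison,
            "irr_pre": self.irr_pre.irr,
            "irr_pre_lo": self.irr_pre.ci95[0], "irr_pre_hi": self.irr_pre.ci95[1],
            "irr_post": self.irr_post.irr,
            "irr_post_lo": self.irr_post.ci95[0], "irr_post_hi": self.irr_post.ci95[1],
            "ratio": self.ratio,
            "ratio_lo": self.ratio_ci95[0], "ratio_hi": self.ratio_ci95[1],
            "significant": self.significant,
        }


def build_pre_period(persons: pd.DataFrame, events: pd.DataFrame, outcome: str,
                     post_followup_days: pd.Series,
                     lookback_days: int = 365,
                     components: list[str] | None = None) -> tuple[pd.DataFrame, int]:
    """Person-period table for the pre-exposure window.

    The window is ``[T0 - L_i, T0)`` with ``L_i`` the person's post-exposure
    follow-up; persons with the outcome within ``lookback_days`` before the
    window start are excluded.  Returns ``(table, n_excluded_for_history)``;
    the table has person_id, group, care_setting, events (0/1) and
    persontime (days, time to first in-window occurrence or the full window).
    """
    outcomes = components if components is not None else [outcome]
    first = (events[events["outcome"].isin(outcomes)]
             .groupby("person_id")["event_date"].min())

    df = persons.loc[persons["person_id"].isin(post_followup_days.index)].copy()
    L = df["person_id"].map(post_followup_days).astype(float)
    window_start = df["t0"] - pd.to_timedelta(L, unit="D")
    ev_date = df["person_id"].map(first)

    hist_start = window_start - pd.Timedelta(days=lookback_days)
    history = ev_date.notna() & (ev_date >= hist_start) & (ev_date < window_start)
    n_excluded = int(history.sum())
    df, L = df[~history], L[~history]
    window_start, ev_date = window_start[~history], ev_date[~history]

    in_window = ev_date.notna() & (ev_date >= window_start) & (ev_date < df["t0"])
    t_event = (ev_date - window_start).dt.days.astype(float)
    persontime = np.where(in_window, t_event, L)
    # degenerate zero-length windows contribute nothing
    table = pd.DataFrame({
        "person_id": df["person_id"].to_numpy(),
        "group": df["group"].to_numpy(),
        "care_setting": df["care_setting"].to_numpy(),
        "events": in_window.to_numpy().astype(int),
        "persontime": persontime,
    })
    table = table[table["persontime"] > 0].reset_index(drop=True)
    return table, n_excluded


def incident_rate_ratio(events, persontime, exposed_mask, weights=None) -> IRRResult:
    """Weighted IRR with a log-scale robust (Poisson-type) variance:
    ``var(log rate) = sum(w^2 e) / (sum(w e))^2`` per arm."""
    e = np.asarray(events, float)
    pt = np.asarray(persontime, float)
    g = np.asarray(exposed_mask).astype(bool)
    w = np.ones_like(e) if weights is None else np.asarray(weights, float)

    def rate(mask):
        we = float((w[mask] * e[mask]).sum())
        wt = float((w[mask] * pt[mask]).sum())
        if we == 0:
            raise ValueError("zero weighted events in one arm")
        var_log = float((w[mask] ** 2 * e[mask]).sum()) / we ** 2
        return we / wt, var_log, we

    r1, v1, e1 = rate(g)
    r0, v0, e0 = rate(~g)
    irr = r1 / r0
    se = float(np.sqrt(v1 + v0))
    return IRRResult(
        irr=float(irr), log_se=se,
        ci95=(float(irr * np.exp(-Z95 * se)), float(irr * np.exp(Z95 * se))),
        events_exposed=e1, events_control=e0,
        persontime_exposed=float((w[g] * pt[g]).sum()),
        persontime_control=float((w[~g] * pt[~g]).sum()),
    )


def did_ratio(irr_pre: IRRResult, irr_post: IRRResult, outcome: str = "",
              comparison: str = "") -> DiDResult:
    """Ratio of post- to pre-period IRRs; CI by log-scale variance addition
    (periods treated as independent)."""
    for r in (irr_pre, irr_post):
        if r.irr <= 0:
            raise ValueError("IRRs must be positive")
    ratio = irr_post.irr / irr_pre.irr
    se = float(np.sqrt(irr_pre.log_se ** 2 + irr_post.log_se ** 2))
    return DiDResult(
        outcome=outcome, comparison=comparison,
        irr_pre=irr_pre, irr_post=irr_post, ratio=float(ratio),
        ratio_ci95=(float(ratio * np.exp(-Z95 * se)), float(ratio * np.exp(Z95 * se))),
    )


def did_ratio_bootstrap(pre: pd.DataFrame, post: pd.DataFrame,
                        weights_pre, weights_post, resamples: int = 500,
                        seed: int = 0, outcome: str = "",
                        comparison: str = "") -> DiDResult:
    """Ratio of IRRs with a person-level bootstrap CI.

    Persons appearing in both periods are resampled jointly, which honors the
    pre/post correlation the analytic variance ignores."""
    if resamples < 2:
        raise ValueError("resamples must be >= 2")
    ids = pd.Index(pd.unique(np.concatenate([pre["person_id"], post["person_id"]])))
    pre_i = ids.get_indexer(pre["person_id"])
    post_i = ids.get_indexer(post["person_id"])
    wpre = np.ones(len(pre)) if weights_pre is None else np.asarray(weights_pre, float)
    wpost = np.ones(len(post)) if weights_post is None else np.asarray(weights_post, float)
    gpre = (pre["group"] == "exposed").to_numpy()
    gpost = (post["group"] == "exposed").to_numpy()

    point_pre = incident_rate_ratio(pre["events"], pre["persontime"], gpre, wpre)
    point_post = incident_rate_ratio(post["events"], post["persontime"], gpost, wpost)
    base = did_ratio(point_pre, point_post, outcome, comparison)

    rng = np.random.default_rng(seed)
    mult = rng.multinomial(len(ids), np.full(len(ids), 1.0 / len(ids)),
                           size=resamples).astype(float)
    ratios = np.empty(resamples)
    for b in range(resamples):
        try:
            rp = incident_rate_ratio(pre["events"], pre["persontime"], gpre,
                                     wpre * mult[b, pre_i])
            ro = incident_rate_ratio(post["events"], post["persontime"], gpost,
                                     wpost * mult[b, post_i])
            ratios[b] = ro.irr / rp.irr
        except ValueError:
            ratios[b] = np.nan
    ratios = ratios[np.isfinite(ratios)]
    ci = (float(np.percentile(ratios, 2.5)), float(np.percentile(ratios, 97.5)))
    return DiDResult(outcome=outcome, comparison=comparison,
                     irr_pre=point_pre, irr_post=point_post,
                     ratio=base.ratio, ratio_ci95=ci)
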