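"""Weighted cause-specific survival estimation.

Implements the weighted Cox partial likelihood (Efron tie handling) with a
cluster-robust sandwich variance, the weighted Aalen–Johansen cumulative
incidence with death as a competing event, 12-month burdens / excess burdens
per 1,000 persons with person-level bootstrap intervals, censoring at
post-baseline events (e.g. vaccination), and a time-varying-covariate variant.

The partial-likelihood fitter is written in-package so that replicate-based
validation at n ~ 10^5 stays fast; it is cross-validated against lifelines in
the test suite.  Score residuals for the sandwich use the standard
counting-process accumulator with Efron-averaged risk-set means (exact in the
absence of ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

Z95 = 1.959963984540054


# --------------------------------------------------------------------------
# Cox partial likelihood
# --------------------------------------------------------------------------

@dataclass
class CoxFit:
    params: np.ndarray
    se: np.ndarray           # model-based
    robust_se: np.ndarray    # sandwich
    cov: np.ndarray          # robust covariance
    n: int
    n_events: float


def _prepare(X, time, event, weights, entry):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, dtype=float)
    s = np.zeros_like(t) if entry is None else np.asarray(entry, dtype=float)
    if np.any(s >= t):
        raise ValueError("entry times must precede exit times")
    order = np.argsort(t, kind="mergesort")
    return X[order], t[order], d[order], w[order], s[order], order


class _EfronPass:
    """One sweep over the risk sets (descending time), Efron tie handling,
    supporting delayed entry (start < t <= stop risk sets)."""

    def __init__(self, Xs, t, d, w, s, bounds, uniq):
        self.Xs, self.t, self.d, self.w, self.s = Xs, t, d, w, s
        self.bounds, self.uniq = bounds, uniq
        # episode indices ordered by entry time, descending: episodes leave
        # the risk set once the current event time drops to their entry
        self.by_entry = np.argsort(-s, kind="mergesort")

    def __call__(self, beta, want_info=True):
        Xs, t, d, w, s = self.Xs, self.t, self.d, self.w, self.s
        bounds, uniq = self.bounds, self.uniq
        n, p = Xs.shape
        lp = Xs @ beta
        lp -= lp.max()  # guard overflow; the shift cancels in the likelihood
        wr = w * np.exp(lp)
        grad = np.zeros(p)
        info = np.zeros((p, p))
        ll = 0.0
        S0, S1, S2 = 0.0, np.zeros(p), np.zeros((p, p))
        ptr = 0
        for bi in range(len(uniq) - 1, -1, -1):
            u = uniq[bi]
            blk = slice(bounds[bi], bounds[bi + 1])
            xb = Xs[blk]
            wrb = wr[blk]
            S0 += wrb.sum()
            S1 += wrb @ xb
            if want_info:
                S2 += (xb * wrb[:, None]).T @ xb
            # drop episodes whose entry is at or after the current event time
            while ptr < n and s[self.by_entry[ptr]] >= u:
                i = self.by_entry[ptr]
                S0 -= wr[i]
                S1 -= wr[i] * Xs[i]
                if want_info:
                    S2 -= wr[i] * np.outer(Xs[i], Xs[i])
                ptr += 1
            ev = d[blk] > 0
            if not ev.any():
                continue
            xD, wD_each, rD = xb[ev], w[blk][ev], wrb[ev]
            dd = int(ev.sum())
            wD = wD_each.sum()
            s0D, s1D = rD.sum(), rD @ xD
            f = np.arange(dd) / dd
            denom = S0 - f * s0D
            xbar = (S1[None, :] - f[:, None] * s1D[None, :]) / denom[:, None]
            grad += wD_each @ xD - (wD / dd) * xbar.sum(axis=0)
            ll += wD_each @ lp[blk][ev] - (wD / dd) * np.log(denom).sum()
            if want_info:
                s2D = (xD * rD[:, None]).T @ xD
                inv = 1.0 / denom
                term = S2 * inv.sum() - s2D * (f * inv).sum() - xbar.T @ xbar
                info += (wD / dd) * term
        return ll, grad, info

    def score_residuals(self, beta):
        """Per-episode score residuals via the counting-process accumulator
        with Efron-averaged risk-set means (exact without ties)."""
        Xs, t, d, w, s = self.Xs, self.t, self.d, self.w, self.s
        bounds, uniq = self.bounds, self.uniq
        n, p = Xs.shape
        lp = Xs @ beta
        lp -= lp.max()
        r = np.exp(lp)
        wr = w * r
        K = len(uniq)
        a = np.zeros(K)
        b = np.zeros((K, p))
        xbar_avg = np.zeros((K, p))
        S0, S1 = 0.0, np.zeros(p)
        ptr = 0
        for bi in range(K - 1, -1, -1):
            u = uniq[bi]
            blk = slice(bounds[bi], bounds[bi + 1])
            xb = Xs[blk]
            wrb = wr[blk]
            S0 += wrb.sum()
            S1 += wrb @ xb
            while ptr < n and s[self.by_entry[ptr]] >= u:
                i = self.by_entry[ptr]
                S0 -= wr[i]
                S1 -= wr[i] * Xs[i]
                ptr += 1
            ev = d[blk] > 0
            if not ev.any():
                continue
            rD = wrb[ev]
            dd = int(ev.sum())
            wD = w[blk][ev].sum()
            f = np.arange(dd) / dd
            denom = S0 - f * rD.sum()
            xbar = (S1[None, :] - f[:, None] * (rD @ xb[ev])[None, :]) / denom[:, None]
            inv = 1.0 / denom
            a[bi] = (wD / dd) * inv.sum()
            b[bi] = (wD / dd) * (xbar * inv[:, None]).sum(axis=0)
            xbar_avg[bi] = xbar.mean(axis=0)
        A = np.concatenate([[0.0], np.cumsum(a)])
        B = np.concatenate([np.zeros((1, p)), np.cumsum(b, axis=0)], axis=0)
        ti = np.searchsorted(uniq, t, side="right")
        si = np.searchsorted(uniq, s, side="right")
        dA = A[ti] - A[si]
        dB = B[ti] - B[si]
        U = -(r[:, None]) * (Xs * dA[:, None] - dB)
        evt = d > 0
        U[evt] += Xs[evt] - xbar_avg[ti[evt] - 1]
        return U


def coxph(X, time, event, weights=None, entry=None, cluster=None,
          max_iter=50, tol=1e-9) -> CoxFit:
    """Weighted Cox regression, Efron ties, robust sandwich variance.

    ``X`` is (n, p); ties are handled by the (weighted) Efron approximation,
    matching R's ``survival::coxph``.  ``entry`` enables delayed-entry
    (start, stop] episodes for time-varying covariates; ``cluster`` groups
    episodes of the same person for the sandwich.  By default every row is
    its own cluster (appropriate for estimated per-person weights).
    """
    Xs, t, d, w, s, order = _prepare(X, time, event, weights, entry)
    n, p = Xs.shape
    if d.sum() == 0:
        raise ValueError("no events in the data")
    uniq, starts = np.unique(t, return_index=True)
    bounds = np.append(starts, n)
    sweep = _EfronPass(Xs, t, d, w, s, bounds, uniq)

    beta = np.zeros(p)
    for _ in range(max_iter):
        ll, grad, info = sweep(beta)
        if np.abs(grad).max() < tol * max(1.0, d.sum()):
            break
        step = np.linalg.solve(info, grad)
        shrink, cand = 1.0, beta + step
        while sweep(cand, want_info=False)[0] < ll - 1e-12 and shrink > 1e-4:
            shrink /= 2.0
            cand = beta + shrink * step
        beta = cand
        if np.abs(shrink * step).max() < tol:
            break
    _, _, info = sweep(beta)

    cov_model = np.linalg.inv(info)
    U = sweep.score_residuals(beta) * w[:, None]
    if cluster is not None:
        cl = np.asarray(cluster)[order]
        U = pd.DataFrame(U).groupby(cl).sum().to_numpy()
    meat = U.T @ U
    cov_robust = cov_model @ meat @ cov_model
    return CoxFit(
        params=beta,
        se=np.sqrt(np.diag(cov_model)),
        robust_se=np.sqrt(np.diag(cov_robust)),
        cov=cov_robust,
        n=n,
        n_events=float(d.sum()),
    )


# --------------------------------------------------------------------------
# Hazard-ratio interface
# --------------------------------------------------------------------------

@dataclass
class HazardResult:
    outcome: str
    comparison: str
    hr: float
    log_hr_se: float
    ci95: tuple[float, float]
    n_exposed: int
    n_control: int
    events_exposed: float
    events_control: float

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return lo > 1.0 or hi < 1.0

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome, "comparison": self.comparison,
            "hr": self.hr, "ci_low": self.ci95[0], "ci_high": self.ci95[1],
            "log_hr_se": self.log_hr_se, "n_exposed": self.n_exposed,
            "n_control": self.n_control, "events_exposed": self.events_exposed,
            "events_control": self.events_control, "significant": self.significant,
        }


def _exposed_mask(data: pd.DataFrame) -> np.ndarray:
    if "exposed" in data.columns:
        return data["exposed"].to_numpy(bool)
    return (data["group"] == "exposed").to_numpy()


def fit_weighted_cox(data: pd.DataFrame, weights=None,
                     covariates: pd.DataFrame | None = None,
                     outcome: str = "", comparison: str = "") -> HazardResult:
    """Cause-specific hazard ratio of exposure with inverse-probability
    weights and a robust sandwich variance.

    Deaths censor non-death outcomes (they enter as ``event = 0`` rows, which
    is exactly the cause-specific risk-set convention).  Supplying
    ``covariates`` gives the doubly robust variant (covariate adjustment on
    top of the weights).
    """
    g = _exposed_mask(data).astype(float)
    ev = data["event"].to_numpy(float)
    for label, mask in (("exposed", g > 0), ("control", g == 0)):
        if ev[mask].sum() == 0:
            raise ValueError(f"no events in the {label} stratum")
    if covariates is not None:
        X = np.column_stack([g, np.asarray(covariates, dtype=float)])
    else:
        X = g[:, None]
    fit = coxph(X, data["time"].to_numpy(float), ev, weights)
    log_hr, se = fit.params[0], fit.robust_se[0]
    return HazardResult(
        outcome=outcome, comparison=comparison,
        hr=float(np.exp(log_hr)), log_hr_se=float(se),
        ci95=(float(np.exp(log_hr - Z95 * se)), float(np.exp(log_hr + Z95 * se))),
        n_exposed=int((g > 0).sum()), n_control=int((g == 0).sum()),
        events_exposed=float(ev[g > 0].sum()), events_control=float(ev[g == 0].sum()),
    )


# --------------------------------------------------------------------------
# Cumulative incidence (Aalen–Johansen) and burdens
# --------------------------------------------------------------------------

def aalen_johansen(time, event, death, weights=None, horizon_days: float = 365.0) -> float:
    """Weighted Aalen–Johansen cumulative incidence of the outcome at the
    horizon, treating death as a competing event.  With no competing events
    this reduces exactly to 1 - Kaplan-Meier."""
    t = np.asarray(time, float)
    if horizon_days > t.max():
        raise ValueError("horizon exceeds the longest follow-up")
    W = (np.ones_like(t) if weights is None else np.asarray(weights, float))[None, :]
    return float(_aj_cif_multi(t, np.asarray(event, float), np.asarray(death, float),
                               W, horizon_days)[0])


def _aj_cif_multi(t, event, death, W, horizon):
    """Aalen–Johansen CIF at ``horizon`` for each row of the weight matrix W."""
    order = np.argsort(t, kind="mergesort")
    t, event, death = t[order], event[order], death[order]
    W = W[:, order]
    uniq, starts = np.unique(t, return_index=True)
    keep = uniq <= horizon
    # weighted counts per unique time
    dN1 = np.add.reduceat(W * event[None, :], starts, axis=1)[:, keep]
    dNd = np.add.reduceat(W * death[None, :], starts, axis=1)[:, keep]
    removed = np.add.reduceat(W, starts, axis=1)
    total = W.sum(axis=1, keepdims=True)
    Y = total - np.concatenate(
        [np.zeros((W.shape[0], 1)), np.cumsum(removed, axis=1)[:, :-1]], axis=1
    )[:, keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_any = np.where(Y > 0, (dN1 + dNd) / Y, 0.0)
        frac1 = np.where(Y > 0, dN1 / Y, 0.0)
    S = np.cumprod(1.0 - frac_any, axis=1)
    S_prev = np.concatenate([np.ones((W.shape[0], 1)), S[:, :-1]], axis=1)
    return (S_prev * frac1).sum(axis=1)


@dataclass
class BurdenResult:
    outcome: str
    burden_exposed: float
    burden_exposed_ci: tuple[float, float]
    burden_control: float
    burden_control_ci: tuple[float, float]
    excess_burden: float
    excess_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "burden_exposed": self.burden_exposed,
            "burden_exposed_lo": self.burden_exposed_ci[0],
            "burden_exposed_hi": self.burden_exposed_ci[1],
            "burden_control": self.burden_control,
            "burden_control_lo": self.burden_control_ci[0],
            "burden_control_hi": self.burden_control_ci[1],
            "excess_burden": self.excess_burden,
            "excess_lo": self.excess_ci[0],
            "excess_hi": self.excess_ci[1],
        }


def estimate_cif(data: pd.DataFrame, weights=None, horizon_days: float = 365.0) -> dict:
    """Weighted cumulative incidence at the horizon per arm, scaled x1,000."""
    g = _exposed_mask(data)
    w = np.ones(len(data)) if weights is None else np.asarray(weights, float)
    out = {}
    for label, mask in (("exposed", g), ("control", ~g)):
        sub = data[mask]
        out[label] = 1000.0 * aalen_johansen(
            sub["time"], sub["event"], sub["death"], w[mask], horizon_days)
    return out


def excess_burden(data: pd.DataFrame, weights=None, horizon_days: float = 365.0,
                  resamples: int = 500, seed: int = 0,
                  outcome: str = "") -> BurdenResult:
    """Burdens per 1,000 at the horizon and their difference, with percentile
    intervals from a person-level bootstrap (resampling within each arm)."""
    if resamples < 2:
        raise ValueError("resamples must be >= 2")
    g = _exposed_mask(data)
    w = np.ones(len(data)) if weights is None else np.asarray(weights, float)
    rng = np.random.default_rng(seed)
    point, boots = {}, {}
    for label, mask in (("exposed", g), ("control", ~g)):
        sub = data[mask]
        t = sub["time"].to_numpy(float)
        e = sub["event"].to_numpy(float)
        dth = sub["death"].to_numpy(float)
        wm = w[mask]
        point[label] = 1000.0 * aalen_johansen(t, e, dth, wm, horizon_days)
        m = rng.multinomial(len(sub), np.full(len(sub), 1.0 / len(sub)),
                            size=resamples).astype(float)
        boots[label] = 1000.0 * _aj_cif_multi(t, e, dth, m * wm[None, :], horizon_days)
    diff = boots["exposed"] - boots["control"]

    def ci(v):
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    return BurdenResult(
        outcome=outcome,
        burden_exposed=point["exposed"], burden_exposed_ci=ci(boots["exposed"]),
        burden_control=point["control"], burden_control_ci=ci(boots["control"]),
        excess_burden=point["exposed"] - point["control"], excess_ci=ci(diff),
    )


# --------------------------------------------------------------------------
# Censoring events and time-varying covariates
# --------------------------------------------------------------------------

def censor_at(data: pd.DataFrame, censor_dates: pd.Series) -> tuple[pd.DataFrame, int]:
    """Censor follow-up at a per-person event date (e.g. first vaccination).

    ``censor_dates`` maps person_id -> date (NaT/absent = no censoring).
    Events after the censoring time are removed; persons censored before
    entry are dropped and counted in the returned drop count."""
    out = data.copy()
    cd = out["person_id"].map(censor_dates)
    days = (pd.to_datetime(cd) - pd.to_datetime(out["entry_date"])).dt.days.astype(float)
    days = days.fillna(np.inf).to_numpy()
    drop = days <= 0
    out = out[~drop].copy()
    days = days[~drop]
    clipped = days < out["time"].to_numpy()
    out.loc[clipped, "event"] = 0
    out.loc[clipped, "death"] = 0
    out["time"] = np.minimum(out["time"].to_numpy(), days)
    return out.reset_index(drop=True), int(drop.sum())


def episode_split(data: pd.DataFrame, switch_dates: pd.Series,
                  weights=None) -> pd.DataFrame:
    """Long-format (start, stop] episodes with a 0->1 switching indicator."""
    g = _exposed_mask(data).astype(float)
    w = np.ones(len(data)) if weights is None else np.asarray(weights, float)
    sw = (pd.to_datetime(data["person_id"].map(switch_dates))
          - pd.to_datetime(data["entry_date"])).dt.days.astype(float)
    sw = sw.fillna(np.inf).to_numpy()
    t = data["time"].to_numpy(float)
    ev = data["event"].to_numpy(float)
    rows = []
    for i in range(len(data)):
        if sw[i] <= 0:
            rows.append((i, 0.0, t[i], ev[i], g[i], 1.0, w[i]))
        elif sw[i] >= t[i]:
            rows.append((i, 0.0, t[i], ev[i], g[i], 0.0, w[i]))
        else:
            rows.append((i, 0.0, sw[i], 0.0, g[i], 0.0, w[i]))
            rows.append((i, sw[i], t[i], ev[i], g[i], 1.0, w[i]))
    return pd.DataFrame(rows, columns=["id", "start", "stop", "event", "exposed",
                                       "switched", "w"])


def fit_time_varying(data: pd.DataFrame, weights=None,
                     switch_dates: pd.Series | None = None,
                     outcome: str = "", comparison: str = "") -> HazardResult:
    """Exposure HR adjusted for a 0->1 time-varying indicator via an
    episode-split delayed-entry representation; episodes of the same person
    form one cluster in the sandwich variance."""
    long = episode_split(data, switch_dates, weights)
    if long["switched"].std() == 0:
        if long["switched"].iloc[0] == 1.0:
            raise ValueError(
                "time-varying indicator is aliased (switched for everyone "
                "from entry; indistinguishable from baseline)")
        cols = ["exposed"]  # nobody ever switches: degenerate covariate
    else:
        cols = ["exposed", "switched"]
    ev = data["event"].to_numpy(float)
    g = _exposed_mask(data).astype(float)
    fit = coxph(long[cols].to_numpy(),
                long["stop"], long["event"], long["w"],
                entry=long["start"], cluster=long["id"])
    log_hr = float(fit.params[0])
    se = float(fit.robust_se[0])
    return HazardResult(
        outcome=outcome, comparison=comparison,
        hr=float(np.exp(log_hr)), log_hr_se=se,
        ci95=(float(np.exp(log_hr - Z95 * se)), float(np.exp(log_hr + Z95 * se))),
        n_exposed=int((g > 0).sum()), n_control=int((g == 0).sum()),
        events_exposed=float(ev[g > 0].sum()), events_control=float(ev[g == 0].sum()),
    )
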