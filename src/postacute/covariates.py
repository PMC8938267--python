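"""Design-matrix construction.

Pre-defined covariates with within-group conditional-mean imputation and
restricted cubic spline expansion, plus algorithmic selection of sparse
high-dimensional codes ranked by univariate relative risk against exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: quantile positions of the spline knots, following common practice for
#: restricted cubic splines
_KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def impute_conditional_mean(values: pd.Series, group_labels: pd.Series) -> pd.Series:
    """Replace missing entries by the mean of observed values within the same
    exposure group; observed entries are untouched."""
    values = pd.Series(values).astype(float)
    groups = pd.Series(group_labels, index=values.index)
    out = values.copy()
    for g, idx in values.groupby(groups).groups.items():
        chunk = values.loc[idx]
        if chunk.notna().sum() == 0:
            raise ValueError(f"group {g!r} has no observed values to impute from")
        out.loc[idx] = chunk.fillna(chunk.mean())
    return out


def rcs_basis(x, n_knots: int = 4, knots=None) -> tuple[np.ndarray, np.ndarray]:
    """Restricted cubic spline basis (linear beyond the boundary knots).

    Returns ``(basis, knots)`` where basis has ``n_knots - 1`` columns, the
    first being the untransformed linear term.  Uses the standard
    truncated-power construction with knots at conventional quantiles.
    """
    x = np.asarray(x, dtype=float)
    if n_knots < 3:
        raise ValueError("n_knots must be >= 3")
    if knots is None:
        if np.unique(x).size < n_knots:
            raise ValueError("fewer distinct values than knots")
        qs = _KNOT_QUANTILES.get(n_knots, tuple(np.linspace(0.05, 0.95, n_knots)))
        knots = np.quantile(x, qs)
    knots = np.asarray(knots, dtype=float)
    if np.unique(knots).size != len(knots):
        raise ValueError("knots are not distinct")
    k = len(knots)
    t1, tk1, tk = knots[0], knots[-2], knots[-1]
    scale = (tk - t1) ** 2

    def cube(u):
        return np.clip(u, 0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (cube(x - tj)
                - cube(x - tk1) * (tk - tj) / (tk - tk1)
                + cube(x - tk) * (tk1 - tj) / (tk - tk1)) / scale
        cols.append(term)
    return np.column_stack(cols), knots


@dataclass
class HighDimSelection:
    """Outcome of the univariate relative-risk screen over sparse codes."""

    candidates: pd.DataFrame  # domain, code, count_exposed, count_control, rr
    selected: list[str] = field(default_factory=list)
    k: int = 100
    min_count: int = 100


def rank_high_dim(codes: pd.DataFrame, exposure: pd.Series, min_count: int = 100,
                  k: int = 100, ranking: str = "abs_log") -> HighDimSelection:
    """Screen sparse binary codes by univariate relative risk against exposure.

    ``codes`` is the long-format occurrence table (person_id, domain, code),
    already restricted to the covariate-assessment window; ``exposure`` maps
    person_id -> True (exposed) / False (comparison group).  Codes occurring
    in at least ``min_count`` persons *within each group* are candidates; the
    top ``k`` by ``|log RR|`` (default) or by raw RR are selected, ties broken
    lexicographically by (domain, code).  A continuity correction of 0.5 is
    applied to zero occurrence cells.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    exposure = pd.Series(exposure)
    n_exp = int(exposure.sum())
    n_ctl = int((~exposure.astype(bool)).sum())
    if n_exp == 0 or n_ctl == 0:
        raise ValueError("both exposure groups must be non-empty")

    occ = codes[codes["person_id"].isin(exposure.index)]
    occ = occ.drop_duplicates(["person_id", "domain", "code"])
    is_exp = occ["person_id"].map(exposure).astype(bool)
    tab = (occ.assign(exp=is_exp.to_numpy())
              .groupby(["domain", "code"])["exp"]
              .agg(count_exposed="sum", total="count")
              .reset_index())
    tab["count_control"] = tab["total"] - tab["count_exposed"]
    tab = tab.drop(columns="total")
    tab = tab[(tab["count_exposed"] >= min_count) & (tab["count_control"] >= min_count)]

    a = tab["count_exposed"].to_numpy(float)
    b = tab["count_control"].to_numpy(float)
    zero = (a == 0) | (b == 0)
    a = np.where(zero, a + 0.5, a)
    b = np.where(zero, b + 0.5, b)
    tab["rr"] = (a / n_exp) / (b / n_ctl)
    tab["abs_log_rr"] = np.abs(np.log(tab["rr"]))

    sort_key = "abs_log_rr" if ranking == "abs_log" else "rr"
    tab = tab.sort_values([sort_key, "domain", "code"],
                          ascending=[False, True, True]).reset_index(drop=True)
    selected = tab["code"].head(k).tolist()
    return HighDimSelection(candidates=tab, selected=selected, k=k, min_count=min_count)


def code_indicator_matrix(codes: pd.DataFrame, person_ids, selected: list[str]) -> pd.DataFrame:
    """0/1 occurrence matrix of the selected codes for the given persons."""
    idx = pd.Index(person_ids, name="person_id")
    mat = pd.DataFrame(0.0, index=idx, columns=[f"hd_{c}" for c in selected])
    occ = codes[codes["code"].isin(selected) & codes["person_id"].isin(idx)]
    occ = occ.drop_duplicates(["person_id", "code"])
    for code, chunk in occ.groupby("code"):
        mat.loc[mat.index.isin(chunk["person_id"]), f"hd_{code}"] = 1.0
    return mat


DEFAULT_CONTINUOUS = ("age", "adi", "bmi", "egfr", "sbp", "dbp")
DEFAULT_LOG1P = ("outpatient_count", "inpatient_count")
DEFAULT_CATEGORICAL = ("race", "sex", "smoking")
DEFAULT_FLAGS = ("long_term_care", "cancer", "ckd", "chronic_lung_disease",
                 "dementia", "diabetes", "dysautonomia", "hyperlipidemia",
                 "hypertension")


def build_design_matrix(persons: pd.DataFrame,
                        continuous=DEFAULT_CONTINUOUS,
                        log1p=DEFAULT_LOG1P,
                        categorical=DEFAULT_CATEGORICAL,
                        flags=DEFAULT_FLAGS,
                        codes: pd.DataFrame | None = None,
                        selection: HighDimSelection | None = None,
                        n_knots: int = 4,
                        group_col: str = "group") -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row per person: imputed + spline-expanded continuous covariates,
    reference-coded categorical indicators, comorbidity flags, and selected
    code indicators.  Returns ``(X, metadata)``; raises on residual missing
    values.
    """
    blocks: list[pd.DataFrame] = []
    meta: list[tuple[str, str, str]] = []
    idx = persons.index

    def add_spline(name: str, raw: pd.Series, source: str) -> None:
        filled = impute_conditional_mean(raw, persons[group_col])
        try:
            basis, _ = rcs_basis(filled.to_numpy(), n_knots=n_knots)
        except ValueError:
            # too few distinct values / coincident knots: keep the linear term
            basis = filled.to_numpy()[:, None]
        cols = [name if j == 0 else f"{name}_rcs{j}" for j in range(basis.shape[1])]
        blocks.append(pd.DataFrame(basis, index=idx, columns=cols))
        meta.extend((c, source, "spline") for c in cols)

    for name in continuous:
        add_spline(name, persons[name].astype(float), "predefined")
    for name in log1p:
        add_spline(f"log1p_{name}", np.log1p(persons[name].astype(float)), "predefined")
    for name in categorical:
        dummies = pd.get_dummies(persons[name], prefix=name, drop_first=True, dtype=float)
        blocks.append(dummies)
        meta.extend((c, "predefined", "indicator") for c in dummies.columns)
    for name in flags:
        blocks.append(persons[[name]].astype(float))
        meta.append((name, "predefined", "flag"))
    if selection is not None and selection.selected:
        if codes is None:
            raise ValueError("codes table required when a selection is supplied")
        mat = code_indicator_matrix(codes, persons["person_id"], selection.selected)
        mat.index = idx
        blocks.append(mat)
        meta.extend((c, "high_dim", "flag") for c in mat.columns)

    X = pd.concat(blocks, axis=1)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"residual missing values in design matrix columns {bad}")
    variable = X.std(axis=0) > 0
    X = X.loc[:, variable]
    metadata = pd.DataFrame(meta, columns=["column", "source", "kind"])
    metadata = metadata[metadata["column"].isin(X.columns)].reset_index(drop=True)
    return X.astype(float), metadata
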