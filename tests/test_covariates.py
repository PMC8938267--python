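import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from postacute.covariates import (build_design_matrix, code_indicator_matrix,
                                  impute_conditional_mean, rank_high_dim,
                                  rcs_basis)


class TestImputation:
    def test_group_mean_fills_missing(self):
        x = pd.Series([1.0, 3.0, np.nan])
        g = pd.Series(["a", "a", "a"])
        assert impute_conditional_mean(x, g).tolist() == [1.0, 3.0, 2.0]

    def test_no_missing_is_identity(self):
        x = pd.Series([1.0, 2.0, 3.0])
        out = impute_conditional_mean(x, pd.Series(["a", "b", "a"]))
        assert out.tolist() == x.tolist()

    def test_imputed_values_differ_by_group(self):
        # hand-computed per-group means on a 6-row fixture: a -> 2.0, b -> 10.0
        x = pd.Series([1.0, 3.0, np.nan, 8.0, 12.0, np.nan])
        g = pd.Series(["a", "a", "a", "b", "b", "b"])
        out = impute_conditional_mean(x, g)
        assert out[2] == 2.0 and out[5] == 10.0

    def test_all_missing_group_raises(self):
        with pytest.raises(ValueError, match="no observed"):
            impute_conditional_mean(pd.Series([1.0, np.nan]),
                                    pd.Series(["a", "b"]))


class TestRestrictedCubicSpline:
    def test_first_column_is_linear_term_and_dimension_rule(self):
        x = np.linspace(0, 10, 50)
        for k in (3, 4, 5):
            basis, knots = rcs_basis(x, n_knots=k)
            assert basis.shape == (50, k - 1)
            np.testing.assert_allclose(basis[:, 0], x)

    def test_matches_truncated_power_formula_at_tabulated_points(self):
        """Brute-force evaluation of the textbook restricted-cubic form at
        knots (0,1,2,3): hand-derived values for x = 0.5 and 2.5."""
        basis, _ = rcs_basis(np.array([0.5, 2.5]), knots=[0, 1, 2, 3])
        # x=0.5: ((0.5)^3)/9 for the first interior term, 0 for the second
        np.testing.assert_allclose(basis[0], [0.5, 0.125 / 9, 0.0])
        # x=2.5: ((2.5)^3 - (0.5)^3*3)/9 and ((1.5)^3 - (0.5)^3*2)/9
        np.testing.assert_allclose(basis[1], [2.5, 15.25 / 9, 3.125 / 9])

    def test_linear_beyond_boundary_knots(self):
        x = np.array([4.0, 5.0, 6.0, 7.0])  # all beyond last knot (3)
        basis, _ = rcs_basis(x, knots=[0, 1, 2, 3])
        second_diff = np.diff(basis, n=2, axis=0)
        np.testing.assert_allclose(second_diff, 0.0, atol=1e-10)

    def test_too_few_distinct_values_raises(self):
        with pytest.raises(ValueError):
            rcs_basis(np.array([1.0, 1.0, 2.0, 2.0]), n_knots=4)


def _codes_frame(spec):
    """spec: {code: (n_exposed_with, n_control_with)} over 10+10 persons."""
    rows = []
    for code, (ne, nc) in spec.items():
        for i in range(ne):
            rows.append((f"e{i}", "diagnosis", code))
        for i in range(nc):
            rows.append((f"c{i}", "diagnosis", code))
    return pd.DataFrame(rows, columns=["person_id", "domain", "code"])


EXPOSURE = pd.Series([True] * 10 + [False] * 10,
                     index=[f"e{i}" for i in range(10)] + [f"c{i}" for i in range(10)])


class TestHighDimSelection:
    def test_ranking_by_abs_log_rr_hand_computed(self):
        # RRs: A = (4/10)/(2/10) = 2.0, B = 1.5, C = 0.25
        codes = _codes_frame({"A": (4, 2), "B": (3, 2), "C": (1, 4)})
        sel = rank_high_dim(codes, EXPOSURE, min_count=1, k=2)
        assert sel.selected == ["C", "A"]  # |log .25| > |log 2| > |log 1.5|
        rr = sel.candidates.set_index("code")["rr"]
        assert rr["A"] == pytest.approx(2.0)
        assert rr["C"] == pytest.approx(0.25)

    def test_raw_ranking_orders_by_rr(self):
        codes = _codes_frame({"A": (4, 2), "B": (3, 2), "C": (1, 4)})
        sel = rank_high_dim(codes, EXPOSURE, min_count=1, k=2, ranking="raw")
        assert sel.selected == ["A", "B"]

    def test_min_count_boundary_excludes_99(self):
        n = 150
        exposure = pd.Series([True] * n + [False] * n,
                             index=[f"e{i}" for i in range(n)]
                             + [f"c{i}" for i in range(n)])
        codes = _codes_frame({"X": (99, 120), "Y": (100, 100)})
        sel = rank_high_dim(codes, exposure, min_count=100, k=10)
        assert set(sel.candidates["code"]) == {"Y"}

    def test_k_larger_than_candidates_selects_all(self):
        codes = _codes_frame({"A": (4, 2), "B": (3, 2)})
        sel = rank_high_dim(codes, EXPOSURE, min_count=1, k=50)
        assert len(sel.selected) == 2

    def test_min_count_zero_keeps_every_observed_code(self):
        codes = _codes_frame({"A": (4, 2), "B": (3, 2), "C": (1, 4), "D": (1, 1)})
        sel = rank_high_dim(codes, EXPOSURE, min_count=0, k=1000)
        assert set(sel.candidates["code"]) == {"A", "B", "C", "D"}

    def test_row_permutation_invariance(self):
        codes = _codes_frame({"A": (4, 2), "B": (2, 4), "C": (5, 3), "D": (3, 5)})
        sel1 = rank_high_dim(codes, EXPOSURE, min_count=1, k=3)
        rng = np.random.default_rng(0)
        shuffled = codes.sample(frac=1.0, random_state=5).reset_index(drop=True)
        sel2 = rank_high_dim(shuffled, EXPOSURE, min_count=1, k=3)
        assert sel1.selected == sel2.selected

    def test_tie_break_is_lexicographic(self):
        # A and B have identical RR; A sorts first
        codes = _codes_frame({"B": (4, 2), "A": (4, 2)})
        sel = rank_high_dim(codes, EXPOSURE, min_count=1, k=1)
        assert sel.selected == ["A"]

    def test_nonpositive_k_raises(self):
        with pytest.raises(ValueError):
            rank_high_dim(_codes_frame({"A": (1, 1)}), EXPOSURE, k=0)


class TestDesignMatrix:
    def _persons(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "person_id": [f"p{i}" for i in range(n)],
            "group": np.where(np.arange(n) % 2 == 0, "exposed", "contemporary"),
            "age": rng.normal(60, 10, n),
            "adi": rng.normal(50, 10, n),
            "bmi": np.where(rng.random(n) < 0.1, np.nan, rng.normal(30, 4, n)),
            "egfr": rng.normal(80, 12, n),
            "sbp": rng.normal(130, 15, n),
            "dbp": rng.normal(80, 10, n),
            "outpatient_count": rng.poisson(4, n),
            "inpatient_count": rng.poisson(0.3, n),
            "race": rng.choice(["white", "black", "other"], n),
            "sex": rng.choice(["male", "female"], n),
            "smoking": rng.choice(["current", "former", "never"], n),
            "long_term_care": rng.integers(0, 2, n),
            "cancer": rng.integers(0, 2, n), "ckd": rng.integers(0, 2, n),
            "chronic_lung_disease": rng.integers(0, 2, n),
            "dementia": rng.integers(0, 2, n), "diabetes": rng.integers(0, 2, n),
            "dysautonomia": rng.integers(0, 2, n),
            "hyperlipidemia": rng.integers(0, 2, n),
            "hypertension": rng.integers(0, 2, n),
        })

    def test_no_residual_missingness_and_float_dtype(self):
        X, meta = build_design_matrix(self._persons())
        assert not X.isna().any().any()
        assert (X.dtypes == float).all()
        assert set(meta["column"]) == set(X.columns)

    def test_column_count_matches_hand_count(self):
        """6 continuous splines at 4 knots (3 cols each), race (2) + sex (1)
        + smoking (2) indicators, 9 flags; sparse count covariates fall back
        to a single linear column when knot quantiles coincide."""
        persons = self._persons(n=200, seed=1)
        X, meta = build_design_matrix(persons)
        for name in ("age", "adi", "bmi", "egfr", "sbp", "dbp"):
            cols = [c for c in X.columns if c == name or c.startswith(f"{name}_rcs")]
            assert len(cols) == 3
        for name in ("outpatient_count", "inpatient_count"):
            cols = [c for c in X.columns if name in c]
            assert 1 <= len(cols) <= 3
        assert (meta["kind"] == "indicator").sum() == 5
        assert (meta["kind"] == "flag").sum() == 9

    def test_two_level_categorical_gives_one_indicator(self):
        X, meta = build_design_matrix(self._persons())
        sex_cols = [c for c in X.columns if c.startswith("sex_")]
        assert len(sex_cols) == 1

    def test_selected_codes_appear_as_binary_columns(self):
        persons = self._persons()
        codes = pd.DataFrame({
            "person_id": ["p0", "p1", "p2"], "domain": "diagnosis",
            "code": ["dia_0001", "dia_0001", "dia_0002"],
        })
        sel = rank_high_dim(codes, pd.Series(True, index=persons["person_id"][:30])
                            .reindex(persons["person_id"], fill_value=False),
                            min_count=0, k=5)
        X, meta = build_design_matrix(persons, codes=codes, selection=sel)
        hd = [c for c in X.columns if c.startswith("hd_")]
        assert hd and set(X[hd].stack().unique()) <= {0.0, 1.0}


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_rcs_basis_reproduces_function_values_linearly_within_range(seed):
    """Any linear function of the basis evaluated at the knots interpolates
    a cubic-spline-consistent curve; sanity property: basis is deterministic
    and finite for arbitrary continuous inputs."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=40)
    basis, knots = rcs_basis(x, n_knots=4)
    assert np.isfinite(basis).all()
    b2, _ = rcs_basis(x, knots=knots)
    np.testing.assert_allclose(basis, b2)
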