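"""All-subsets regression: enumeration, fitting, ranking, term expansion."""

import numpy as np
import pandas as pd
import pytest

from springlipids.model_search import (
    enumerate_subsets,
    fit_mlr,
    fit_mlr_extended,
    search,
)

PREDICTORS = ["ph", "temperature", "do_conc", "spc", "orp", "fe2", "sulfide"]


def normal_equations_fit(y, X):
    """Independent closed-form oracle: (X'X)^-1 X'y with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - A @ beta
    tss = np.sum((y - np.mean(y)) ** 2)
    r2 = 1 - (resid @ resid) / tss
    n, p = X.shape
    adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
    return beta, r2, adj


class TestEnumerateSubsets:
    @pytest.mark.parametrize("k, expected", [(1, 1), (3, 7), (7, 127)])
    def test_counts(self, k, expected):
        assert len(enumerate_subsets(PREDICTORS[:k])) == expected

    def test_deterministic_order_by_size_then_name(self):
        subs = enumerate_subsets(["c", "a", "b"])
        assert subs[:3] == [("a",), ("b",), ("c",)]
        assert subs[3] == ("a", "b")
        assert subs == enumerate_subsets(["b", "c", "a"])

    def test_duplicates_and_guardrail(self):
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_subsets(["a", "a"])
        with pytest.raises(ValueError):
            enumerate_subsets([f"p{i}" for i in range(21)])


class TestFitMlr:
    def test_perfect_linear_response(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        y = 3 + 2 * X["a"] - X["b"]
        res = fit_mlr(y, X)
        assert res.r2 == pytest.approx(1.0)
        assert res.adjusted_r2 == pytest.approx(1.0)

    def test_adjusted_r2_uses_the_stated_formula(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(size=30)
        res = fit_mlr(y, X)
        expected = 1 - (1 - res.r2) * (res.n - 1) / (res.n - 3 - 1)
        assert res.adjusted_r2 == pytest.approx(expected, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = (1 + X["a"] - 2 * X["b"] + rng.normal(scale=0.5, size=30)).to_numpy()
        res = fit_mlr(y, X, standardize=False)
        beta, r2, adj = normal_equations_fit(y, X.to_numpy())
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        for j, c in enumerate("abc"):
            assert res.coefficients[c] == pytest.approx(beta[j + 1], abs=1e-10)
        assert res.r2 == pytest.approx(r2, abs=1e-10)
        assert res.adjusted_r2 == pytest.approx(adj, abs=1e-10)

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="b"):
            fit_mlr(rng.normal(size=20), X, standardize=False)

    def test_too_few_cases(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_mlr([1.0, 2.0, 3.0], X)

    def test_nested_r2_never_decreases_adjusted_may(self, ynp41):
        chain = [["ph"], ["ph", "orp"], ["ph", "orp", "spc"],
                 ["ph", "orp", "spc", "sulfide"]]
        r2s = [
            fit_mlr(ynp41["ri_with_cren"], ynp41[c]).r2 for c in chain
        ]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))


class TestExtended:
    def test_term_cardinality(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = rng.normal(size=40)
        res = fit_mlr_extended(y, X, True, True)
        assert len(res.coefficients) == 5  # a, b, a², b², a:b

    def test_quadratic_response_recovered(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"x": rng.uniform(-2, 2, 60)})
        y = X["x"] ** 2
        res = fit_mlr_extended(y, X, include_quadratics=True)
        assert res.r2 == pytest.approx(1.0, abs=1e-8)

    def test_no_flags_is_plain_fit(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(25, 2)), columns=["a", "b"])
        y = rng.normal(size=25)
        assert fit_mlr_extended(y, X) == fit_mlr(y, X)


class TestSearch:
    def test_full_report_and_rank_permutation(self, ynp41):
        rep = search(ynp41, "ri_with_cren", PREDICTORS)
        assert len(rep.models) + len(rep.skipped) == 127
        ranks = sorted(m.rank_by_adj_r2 for m in rep.models)
        assert ranks == list(range(1, len(rep.models) + 1))
        adj = [m.adjusted_r2 for m in rep.models]
        assert adj == sorted(adj, reverse=True)

    def test_rerun_is_deterministic(self, ynp41):
        a = search(ynp41, "ri_with_cren", PREDICTORS)
        b = search(ynp41, "ri_with_cren", PREDICTORS)
        assert [m.predictor_subset for m in a.models] == [
            m.predictor_subset for m in b.models
        ]
        assert a.to_frame().equals(b.to_frame())

    def test_ph_generated_response_puts_ph_in_all_top_models(self, ynp41):
        rng = np.random.default_rng(8)
        df = ynp41.assign(
            resp=2.0 - 0.4 * ynp41["ph"] + rng.normal(scale=0.2, size=len(ynp41))
        )
        rep = search(df, "resp", PREDICTORS)
        top = rep.top_significant()
        assert top and all("ph" in m.predictor_subset for m in top)
        assert rep.inclusion_counts()["ph"] == len(top)

    def test_small_k_matches_independent_lstsq_path(self, ynp41):
        preds = PREDICTORS[:4]
        rep = search(ynp41, "cren_fraction", preds)
        y = ynp41["cren_fraction"].to_numpy()
        for m in rep.models:
            X = ynp41[list(m.predictor_subset)].to_numpy()
            Xs = (X - X.mean(0)) / X.std(0, ddof=1)
            A = np.column_stack([np.ones(len(y)), Xs])
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)  # QR/SVD route
            resid = y - A @ beta
            r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
            n, p = X.shape
            adj = 1 - (1 - r2) * (n - 1) / (n - p - 1)
            assert m.adjusted_r2 == pytest.approx(adj, abs=1e-8)

    def test_constant_response_raises(self, ynp41):
        df = ynp41.assign(flat=0.5)
        with pytest.raises(ValueError, match="constant"):
            search(df, "flat", PREDICTORS)

    def test_tie_break_prefers_smaller_subset(self):
        # exact duplicate predictor values force exact adjusted-R² ties
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"a": rng.normal(size=30)})
        df["y"] = df["a"] + rng.normal(scale=0.1, size=30)
        df["b"] = rng.normal(size=30)
        rep = search(df, "y", ["a", "b"])
        subsets = [m.predictor_subset for m in rep.models]
        assert subsets[0] == ("a",) or subsets[0] == ("a", "b")
        # determinism of ordering among equal-adj entries is by size then name
        assert len(subsets) == len(set(subsets))
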