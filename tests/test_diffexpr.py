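"""Filtering, normalisation, covariate adjustment, Welch test, BH, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import brute_force_bh
from ribostress import diffexpr as de
from ribostress.counts import CountMatrix


def _cm(counts: dict[str, list[int]], groups: list[str]) -> CountMatrix:
    samples = [f"s{i}" for i in range(len(groups))]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=samples).T.astype(np.int64),
        meta=pd.DataFrame({"group": groups}, index=samples),
    )


class TestFilterLowCounts:
    def test_mean_rule_edge_cases(self):
        cm = _cm(
            {"zero": [0, 0, 0, 0], "edge": [5, 5, 5, 5], "keep": [6, 6, 6, 6]},
            ["control", "control", "stress", "stress"],
        )
        out = de.filter_low_counts(cm, threshold=5)
        assert list(out.counts.index) == ["keep"]  # mean exactly 5 is removed

    def test_row_sum_rule(self):
        cm = _cm({"a": [1, 1, 1, 2], "b": [2, 2, 1, 1]}, ["control"] * 2 + ["stress"] * 2)
        out = de.filter_low_counts(cm, threshold=5, mode="row_sum")
        assert list(out.counts.index) == ["b"]  # sum 5 removed, sum 6 kept

    def test_all_removed_warns_not_errors(self):
        cm = _cm({"a": [0, 0, 0, 0]}, ["control", "control", "stress", "stress"])
        with pytest.warns(UserWarning, match="every gene"):
            out = de.filter_low_counts(cm)
        assert out.counts.empty and list(out.meta.index) == list(cm.meta.index)


class TestNormalizeLogCpm:
    def test_zero_count_maps_to_zero_at_unit_pseudocount(self):
        X = de.normalize_log_cpm(pd.DataFrame({"s": [0, 10]}, index=["a", "b"]))
        assert X.loc["a", "s"] == 0.0

    def test_spot_value(self):
        X = de.normalize_log_cpm(
            pd.DataFrame({"s": [100, 999_900]}, index=["a", "rest"])
        )
        assert X.loc["a", "s"] == pytest.approx(np.log2(101), abs=1e-12)

    def test_scale_invariance_exact_at_zero_pseudocount(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [4, 16]}, index=["a", "b"])
        doubled = counts.assign(s1=counts["s1"] * 2)
        a = de.normalize_log_cpm(counts, pseudocount=0)
        b = de.normalize_log_cpm(doubled, pseudocount=0)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_library_size_names_sample(self):
        with pytest.raises(ValueError, match="empty_sample"):
            de.normalize_log_cpm(pd.DataFrame({"ok": [5], "empty_sample": [0]}))


class TestCovariateAdjust:
    def test_no_covariates_is_identity(self):
        X = pd.DataFrame(np.arange(8.0).reshape(2, 4), index=["a", "b"],
                         columns=list("wxyz"))
        assert de.covariate_adjust(X, None) is X

    def test_residuals_orthogonal_to_covariate(self):
        rng = np.random.default_rng(0)
        age = rng.normal(size=20)
        X = pd.DataFrame({f"s{i}": [2 * age[i]] for i in range(20)}, index=["g"])
        covs = pd.DataFrame({"age": age}, index=X.columns)
        resid = de.covariate_adjust(X, covs)
        assert np.abs(resid.to_numpy() @ age).item() < 1e-10

    def test_matches_normal_equations_oracle(self):
        # independent solve via the normal equations on a 5-gene, 8-sample fixture
        rng = np.random.default_rng(42)
        X = pd.DataFrame(rng.normal(size=(5, 8)), index=[f"g{i}" for i in range(5)],
                         columns=[f"s{i}" for i in range(8)])
        covs = pd.DataFrame(rng.normal(size=(8, 2)), index=X.columns, columns=["age", "ph"])
        D = np.column_stack([np.ones(8), covs.to_numpy()])
        beta = np.linalg.solve(D.T @ D, D.T @ X.to_numpy().T)
        expected = X.to_numpy() - (D @ beta).T
        np.testing.assert_allclose(de.covariate_adjust(X, covs).to_numpy(), expected,
                                   atol=1e-10)

    def test_collinear_design_rejected_with_names(self):
        X = pd.DataFrame(np.random.default_rng(1).normal(size=(2, 6)),
                         columns=[f"s{i}" for i in range(6)])
        covs = pd.DataFrame({"age": np.arange(6.0), "age2": 2 * np.arange(6.0)},
                            index=X.columns)
        with pytest.raises(ValueError, match="age2"):
            de.covariate_adjust(X, covs)


class TestBhAdjust:
    def test_single_and_constant_vectors(self):
        assert de.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)
        np.testing.assert_allclose(de.bh_adjust(np.full(5, 0.2)), 0.2)

    def test_worked_example(self):
        np.testing.assert_allclose(
            de.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            de.bh_adjust(np.array([0.5, 1.5]))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, ps):
        p = np.asarray(ps)
        np.testing.assert_allclose(de.bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestDeTest:
    @staticmethod
    def _frame(case, ctrl):
        data = np.concatenate([case, ctrl])[None, :]
        cols = [f"c{i}" for i in range(len(case))] + [f"k{i}" for i in range(len(ctrl))]
        X = pd.DataFrame(data, index=["g"], columns=cols)
        groups = pd.Series(["stress"] * len(case) + ["control"] * len(ctrl), index=cols)
        return X, groups

    def test_welch_statistic_matches_hand_formula(self):
        X, groups = self._frame([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        out = de.de_test(X, groups)
        m1, m2 = 3.5, 2.5
        v1 = v2 = np.var([1, 2, 3, 4], ddof=1)
        t = (m1 - m2) / np.sqrt(v1 / 4 + v2 / 4)
        df = (v1 / 4 + v2 / 4) ** 2 / ((v1 / 4) ** 2 / 3 + (v2 / 4) ** 2 / 3)
        p = 2 * stats.t.sf(abs(t), df)
        assert out.loc["g", "log2FC"] == pytest.approx(1.0)
        assert out.loc["g", "p"] == pytest.approx(p, rel=1e-12)

    def test_null_p_values_are_uniform(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(2000, 40)),
                         columns=[f"s{i}" for i in range(40)])
        groups = pd.Series(["control"] * 20 + ["stress"] * 20, index=X.columns)
        out = de.de_test(X, groups)
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01

    def test_degenerate_zero_variance_gets_machine_minimum_p(self):
        X, groups = self._frame([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        out = de.de_test(X, groups)
        assert out.loc["g", "log2FC"] == 1.0
        assert 0 < out.loc["g", "p"] <= np.finfo(float).tiny

    def test_single_sample_group_rejected(self):
        X, groups = self._frame([1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="2 samples"):
            de.de_test(X, groups)


class TestSelectSignificant:
    @staticmethod
    def _de(p, q, lfc):
        return pd.DataFrame({"log2FC": lfc, "p": p, "q": q, "direction": "ns"},
                            index=[f"g{i}" for i in range(len(p))])

    def test_p_mode_uses_raw_p(self):
        # p = 0.049 with q = 0.2: selected under the raw-p rule only
        table = self._de([0.049], [0.2], [1.0])
        assert de.select_significant(table, mode=de.P_MODE) == ({"g0"}, set())
        assert de.select_significant(table, mode=de.Q_MODE) == (set(), set())

    def test_zero_lfc_excluded_and_empty_table_ok(self):
        table = self._de([0.001, 0.001], [0.001, 0.001], [0.0, -2.0])
        up, down = de.select_significant(table, mode=de.Q_MODE)
        assert up == set() and down == {"g1"}
        empty = self._de([], [], [])
        assert de.select_significant(empty, mode=de.P_MODE) == (set(), set())

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            de.select_significant(self._de([0.5], [0.5], [1.0]), mode="bogus")
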