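"""Renormalization, cohort rules, abundance filter and entropy selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nervede import ExpressionMatrix
from nervede.io_model import SchemaError, normalize_metadata
from nervede.preprocess import (assign_cohorts, confound_summary,
                                filter_expressed, normalized_entropy,
                                renormalize_coding, select_nonubiquitous,
                                select_variable)


def _ann(gene_ids, coding):
    return pd.DataFrame({
        "gene_id": gene_ids,
        "symbol": [g.upper() for g in gene_ids],
        "chromosome": ["1"] * len(gene_ids),
        "is_coding": coding,
    }).set_index("gene_id", drop=False)


class TestRenormalize:
    def test_noncoding_dropped_and_coding_rescaled(self):
        # 2 coding genes (1, 3 TPM) + 1 non-coding (4 TPM): coding values
        # rescale to 250k / 750k and the non-coding row disappears
        m = ExpressionMatrix(["a", "b", "nc"], ["s1"],
                             np.array([[1.0], [3.0], [4.0]]))
        out = renormalize_coding(m, _ann(["a", "b", "nc"], [True, True, False]))
        assert out.gene_ids == ["a", "b"]
        np.testing.assert_allclose(out.values[:, 0], [250_000.0, 750_000.0])

    def test_sample_already_normalized_unchanged(self):
        m = ExpressionMatrix(["a", "b"], ["s1"],
                             np.array([[400_000.0], [600_000.0]]))
        out = renormalize_coding(m, _ann(["a", "b"], [True, True]))
        np.testing.assert_allclose(out.values, m.values)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = ExpressionMatrix([f"g{i}" for i in range(20)], ["s1", "s2", "s3"],
                             rng.gamma(2.0, 10.0, size=(20, 3)))
        ann = _ann(m.gene_ids, [True] * 20)
        once = renormalize_coding(m, ann)
        twice = renormalize_coding(once, ann)
        np.testing.assert_allclose(twice.values, once.values, rtol=1e-12)
        np.testing.assert_allclose(once.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_all_zero_coding_sample_is_error(self):
        m = ExpressionMatrix(["a", "nc"], ["s1"], np.array([[0.0], [5.0]]))
        with pytest.raises(ValueError, match="s1"):
            renormalize_coding(m, _ann(["a", "nc"], [True, False]))

    def test_unannotated_gene_is_error(self):
        m = ExpressionMatrix(["a", "b"], ["s1"], np.array([[1.0], [1.0]]))
        with pytest.raises(SchemaError, match="b"):
            renormalize_coding(m, _ann(["a"], [True]))


def _meta(**overrides):
    row = {"SAMPID": "d", "SEX": "male", "AGE": 50, "MHT1D": "no",
           "MHT2D": "no", "MHARTHTS": "no", "MHRA": "no", "MHSEPSIS": "no",
           "LBHIV1NT": "negative"}
    row.update(overrides)
    return normalize_metadata(pd.DataFrame([row]))


class TestCohortAssignment:
    @pytest.mark.parametrize("overrides,expected,reason", [
        ({}, "BSL", ""),
        ({"MHT2D": "yes"}, "T2D", ""),
        ({"MHARTHTS": "yes"}, "CJP", ""),
        ({"MHRA": "yes"}, "CJP", ""),
        ({"MHARTHTS": "yes", "MHT2D": "yes"}, "EXCLUDED", "joint_pain_and_T2D"),
        ({"MHRA": "yes", "MHT2D": "yes"}, "EXCLUDED", "joint_pain_and_T2D"),
        ({"MHSEPSIS": "yes"}, "EXCLUDED", "sepsis"),
        ({"MHT1D": "yes"}, "EXCLUDED", "type_I_diabetes"),
        ({"LBHIV1NT": "positive"}, "EXCLUDED", "HIV_positive"),
        ({"LBHIV1NT": "not performed"}, "BSL", ""),  # untested HIV stays in
        ({"MHT2D": "unknown"}, "BSL", ""),           # unknown treated as no
    ])
    def test_rules(self, overrides, expected, reason):
        out = assign_cohorts(_meta(**overrides))
        assert out.iloc[0]["cohort"] == expected
        assert out.iloc[0]["exclusion_reason"] == reason

    def test_exhaustive_and_exclusive(self, meta_frame):
        out = assign_cohorts(meta_frame)
        assert len(out) == len(meta_frame)
        assert out["cohort"].isin(["BSL", "CJP", "T2D", "EXCLUDED"]).all()
        excl = out["cohort"] == "EXCLUDED"
        assert (out.loc[excl, "exclusion_reason"] != "").all()
        assert (out.loc[~excl, "exclusion_reason"] == "").all()


class TestConfoundSummary:
    def test_mean_and_sample_sd(self):
        meta = normalize_metadata(pd.DataFrame([
            {"SAMPID": "a", "SEX": "male", "AGE": 40, "MHT1D": "no",
             "MHT2D": "no", "MHARTHTS": "no", "MHRA": "no", "MHSEPSIS": "no",
             "LBHIV1NT": "negative"},
            {"SAMPID": "b", "SEX": "male", "AGE": 60, "MHT1D": "no",
             "MHT2D": "no", "MHARTHTS": "no", "MHRA": "no", "MHSEPSIS": "no",
             "LBHIV1NT": "negative"},
        ]))
        tab = confound_summary(assign_cohorts(meta), meta)
        sub = tab[(tab["cohort"] == "BSL") & (tab["sex"] == "male")
                  & (tab["variable"] == "AGE")]
        assert sub[sub["statistic"] == "mean"]["value"].iloc[0] == pytest.approx(50.0)
        assert sub[sub["statistic"] == "sd"]["value"].iloc[0] == pytest.approx(
            14.142135, abs=1e-5)
        # empty female subcohort reported with count 0
        fem = tab[(tab["sex"] == "female") & (tab["variable"] == "cohort_size")]
        assert (fem["value"] == 0.0).all()


class TestExpressedFilter:
    def test_gene_passing_in_one_sex_is_kept(self):
        # male median 0.6 / max 1.2 passes; female fails; gene kept
        m = ExpressionMatrix(["g"], ["m1", "m2", "m3", "f1", "f2", "f3"],
                             np.array([[0.6, 0.5, 1.2, 0.0, 0.0, 0.2]]))
        groups = {"male": ["m1", "m2", "m3"], "female": ["f1", "f2", "f3"]}
        assert filter_expressed(m, groups).loc["g"]

    def test_all_zero_gene_filtered(self):
        m = ExpressionMatrix(["g"], ["s1", "s2"], np.zeros((1, 2)))
        assert not filter_expressed(m, None).loc["g"]

    def test_boundary_uses_strict_failure(self):
        # median exactly 0.5 and max exactly 1.0 in both sexes -> expressed
        m = ExpressionMatrix(["g"], ["m1", "m2", "f1", "f2"],
                             np.array([[0.0, 1.0, 0.0, 1.0]]))
        groups = {"male": ["m1", "m2"], "female": ["f1", "f2"]}
        assert filter_expressed(m, groups).loc["g"]

    def test_empty_group_is_error(self, small_matrix):
        with pytest.raises(ValueError, match="empty"):
            filter_expressed(small_matrix, {"male": []})

    def test_relaxing_threshold_is_monotone(self):
        rng = np.random.default_rng(3)
        m = ExpressionMatrix([f"g{i}" for i in range(50)],
                             [f"s{j}" for j in range(10)],
                             rng.gamma(1.0, 1.0, size=(50, 10)))
        strict = filter_expressed(m, None, median_min=0.5, max_min=1.0)
        loose = filter_expressed(m, None, median_min=0.25, max_min=0.5)
        assert (loose | ~strict).all()


class TestEntropy:
    def test_uniform_row_has_maximal_entropy(self):
        m = ExpressionMatrix(["g"], list("abcd"), np.full((1, 4), 7.0))
        assert normalized_entropy(m).loc["g"] == pytest.approx(1.0, abs=1e-12)

    def test_single_support_row_has_zero_entropy(self):
        m = ExpressionMatrix(["g"], list("abcd"),
                             np.array([[0.0, 9.0, 0.0, 0.0]]))
        assert normalized_entropy(m).loc["g"] == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_value(self):
        m = ExpressionMatrix(["g"], list("abc"), np.array([[1.0, 1.0, 2.0]]))
        expected = 1.5 / np.log2(3)
        assert normalized_entropy(m).loc["g"] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_row_scores_zero(self):
        m = ExpressionMatrix(["g"], list("abc"), np.zeros((1, 3)))
        assert normalized_entropy(m).loc["g"] == 0.0

    def test_single_sample_is_error(self):
        m = ExpressionMatrix(["g"], ["s"], np.array([[1.0]]))
        with pytest.raises(ValueError):
            normalized_entropy(m)

    @given(arrays(float, (3, 6), elements=st.floats(0.01, 100.0)),
           st.floats(0.1, 50.0))
    def test_scale_and_permutation_invariance(self, vals, c):
        ids = [f"g{i}" for i in range(3)]
        cols = [f"s{j}" for j in range(6)]
        e1 = normalized_entropy(ExpressionMatrix(ids, cols, vals))
        e2 = normalized_entropy(ExpressionMatrix(ids, cols, vals * c))
        perm = np.random.default_rng(0).permutation(6)
        e3 = normalized_entropy(ExpressionMatrix(ids, cols, vals[:, perm]))
        np.testing.assert_allclose(e1, e2, atol=1e-10)
        np.testing.assert_allclose(e1, e3, atol=1e-10)


class TestEntropySelection:
    def test_variable_top_decile_selected(self):
        e = pd.Series(np.linspace(0.05, 0.95, 10), index=[f"g{i}" for i in range(10)])
        expressed = pd.Series(True, index=e.index)
        mask = select_variable(e, expressed, pct=90.0)
        assert int(mask.sum()) == 1 and mask.loc["g9"]

    def test_all_tied_entropies_all_variable_none_testable(self):
        e = pd.Series(0.5, index=[f"g{i}" for i in range(5)])
        expressed = pd.Series(True, index=e.index)
        assert select_variable(e, expressed).all()
        assert not select_nonubiquitous(e, expressed).any()

    def test_nonubiquitous_excludes_high_entropy(self):
        e = pd.Series([0.1, 0.2, 0.3, 0.9], index=list("abcd"))
        expressed = pd.Series(True, index=e.index)
        mask = select_nonubiquitous(e, expressed, pct=75.0)
        assert not mask.loc["d"] and mask.loc[["a", "b", "c"]].all()

    def test_empty_when_nothing_expressed(self):
        e = pd.Series([0.1, 0.9], index=["a", "b"])
        expressed = pd.Series(False, index=e.index)
        assert not select_variable(e, expressed).any()
        assert not select_nonubiquitous(e, expressed).any()

    def test_single_expressed_gene_not_testable(self):
        e = pd.Series([0.4], index=["a"])
        expressed = pd.Series(True, index=e.index)
        assert not select_nonubiquitous(e, expressed).any()
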