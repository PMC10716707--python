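"""Clinical table loading, labeling rules, selection, feature assembly."""

import numpy as np
import pandas as pd
import pytest

from cxrfuse.clinical import (COUNTERFACTUAL_RULE, LabelRule, LabelingError,
                              SchemaError, assemble_final_features,
                              derive_benefit_label, derive_improvement,
                              kbest_select, load_clinical_table)
from cxrfuse.schema import FINAL_FEATURES
from cxrfuse.synthetic import CohortSimParams, generate_clinical_table


@pytest.fixture(scope="module")
def table():
    return generate_clinical_table(CohortSimParams(n_patients=60, seed=1))[0]


class TestLoad:
    def test_round_trip(self, table, tmp_path):
        path = tmp_path / "clinical.csv"
        table.to_csv(path, index=False)
        loaded = load_clinical_table(path)
        assert len(loaded) == 60
        assert set(loaded["dyspnea"].unique()) <= {"yes", "no", "missing"}

    def test_na_symptom_becomes_missing(self, tmp_path):
        t, _ = generate_clinical_table(CohortSimParams(n_patients=3, seed=2))
        t.loc[0, "cough"] = "N/A"
        path = tmp_path / "c.csv"
        t.to_csv(path, index=False)
        assert load_clinical_table(path)["cough"].iloc[0] == "missing"

    def test_missing_mandatory_column_named(self, table, tmp_path):
        path = tmp_path / "broken.csv"
        table.drop(columns=["ko_rdw"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="ko_rdw"):
            load_clinical_table(path)

    def test_unparseable_numeric_names_record(self, table, tmp_path):
        bad = table.copy()
        bad.loc[2, "age"] = "elderly"
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="age"):
            load_clinical_table(path)


class TestImprovement:
    @pytest.mark.parametrize("score, expected",
                             [(0, 0), (6, 0), (7, 1), (10, 1)])
    def test_threshold(self, score, expected):
        assert derive_improvement(score) == expected

    def test_monotone_in_score(self):
        vals = [derive_improvement(s) for s in range(11)]
        assert vals == sorted(vals)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            derive_improvement(11)


class TestBenefitLabel:
    def test_explicit_column_wins(self):
        t = pd.DataFrame({"benefit_label": [1, 0, 1],
                          "cs_use": [0, 0, 0],
                          "radiological_score": [0, 0, 0]})
        np.testing.assert_array_equal(derive_benefit_label(t), [1, 0, 1])

    def test_without_column_and_rule_raises(self):
        t = pd.DataFrame({"cs_use": [1], "radiological_score": [8]})
        with pytest.raises(LabelingError, match="LabelRule"):
            derive_benefit_label(t)

    def test_counterfactual_rule_all_combinations(self):
        t = pd.DataFrame({"cs_use": [1, 1, 0, 0],
                          "radiological_score": [9, 3, 9, 3]})
        got = derive_benefit_label(t, rule=COUNTERFACTUAL_RULE)
        # treated+improved -> 1; treated+not -> 0; untreated+improved -> 0;
        # untreated+not improved -> 1.
        np.testing.assert_array_equal(got, [1, 0, 0, 1])

    def test_incomplete_rule_mapping_rejected(self):
        with pytest.raises(ValueError, match="four"):
            LabelRule(mapping={(1, 1): 1})


class TestKBest:
    def test_perfect_feature_ranks_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=100)
        X = pd.DataFrame({"noise1": rng.random(100),
                          "oracle": y.astype(float),
                          "noise2": rng.random(100)})
        out = kbest_select(X, y, k=1)
        assert out.iloc[0]["feature"] == "oracle"

    def test_k_equals_n_columns_returns_all(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.random((30, 4)), columns=list("abcd"))
        out = kbest_select(X, rng.integers(0, 2, size=30), k=4)
        assert out["selected"].all()

    def test_constant_column_scores_zero(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"flat": np.ones(40), "x": rng.random(40)})
        out = kbest_select(X, rng.integers(0, 2, size=40), k=1)
        row = out[out.feature == "flat"].iloc[0]
        assert row["score"] == 0.0 and row["p_value"] == 1.0

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.random((50, 3)), columns=list("abc"))
        y = rng.integers(0, 2, size=50)
        base = kbest_select(X, y, k=2)
        perm = rng.permutation(50)
        shuffled = kbest_select(X.iloc[perm].reset_index(drop=True), y[perm], k=2)
        pd.testing.assert_frame_equal(base, shuffled)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            kbest_select(pd.DataFrame({"a": [1.0, 2.0]}), [0, 1], k=5)


class TestAssemble:
    def test_default_manifest_gives_21_columns(self, table):
        fm = assemble_final_features(table)
        assert len(fm.columns) == 21
        assert fm.columns == list(FINAL_FEATURES)
        assert all(v == "clinical" for v in fm.provenance.values())

    def test_empty_manifest_rejected(self, table):
        with pytest.raises(ValueError, match="empty"):
            assemble_final_features(table, manifest=[])

    def test_yes_no_encoding(self):
        t = pd.DataFrame({"cough": ["yes", "no", "yes"]})
        fm = assemble_final_features(t, manifest=["cough"])
        np.testing.assert_array_equal(fm.values.ravel(), [1, 0, 1])

    def test_absent_feature_named_in_error(self, table):
        with pytest.raises(SchemaError, match="nonexistent"):
            assemble_final_features(table, manifest=["nonexistent"])

    def test_idempotent_on_own_output(self, table):
        fm = assemble_final_features(table)
        again = assemble_final_features(fm.frame.reset_index(),
                                        manifest=list(fm.columns))
        np.testing.assert_allclose(fm.values, again.values)

    def test_missing_indicator_columns_optional(self, table):
        t = table.copy()
        t.loc[t.index[0], "cough"] = "missing"
        fm = assemble_final_features(t, missing_indicators=True)
        assert "cough__missing" in fm.columns
        assert fm.frame["cough__missing"].iloc[0] == 1
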