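"""Fusion matrices and the randomized-search classifier suite."""

import numpy as np
import pandas as pd
import pytest

from cxrfuse.clinical import FeatureMatrix
from cxrfuse.fusion import (METHODS, SearchSpace, default_search_space, fuse,
                            make_estimator, random_search_cv)


def toy_clinical(ids, n_cols=3, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(rng.random((len(ids), n_cols)),
                         columns=[f"clin{j}" for j in range(n_cols)],
                         index=pd.Index(ids, name="patient_id"))
    return FeatureMatrix(frame=frame,
                         provenance={c: "clinical" for c in frame.columns})


class TestFuse:
    def test_width_sum(self):
        ids = [f"P{i}" for i in range(6)]
        latent = np.random.default_rng(1).random((6, 32))
        fused = fuse(latent, ids, layer=-2, clinical=toy_clinical(ids, 21))
        assert fused.values.shape == (6, 53)
        assert len(fused.latent_columns) == 32
        assert len(fused.clinical_columns) == 21
        assert fused.block_of("latent-2_0") == "latent"
        assert fused.block_of("clin0") == "clinical"

    def test_latent_only_mode(self):
        ids = list(range(5))
        fused = fuse(np.random.default_rng(2).random((5, 14)), ids, layer=-1)
        assert fused.values.shape == (5, 14)
        assert fused.clinical_columns == []

    def test_row_order_invariance_after_id_sort(self):
        ids = ["P3", "P1", "P2"]
        latent = np.random.default_rng(3).random((3, 4))
        a = fuse(latent, ids, layer=-1, clinical=toy_clinical(ids))
        perm = [2, 0, 1]
        b = fuse(latent[perm], [ids[i] for i in perm], layer=-1,
                 clinical=toy_clinical(ids))
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_id_mismatch_lists_offenders(self):
        latent = np.random.default_rng(4).random((3, 4))
        with pytest.raises(ValueError, match="P9"):
            fuse(latent, ["P1", "P2", "P9"], layer=-1,
                 clinical=toy_clinical(["P1", "P2", "P3"]))


def separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.normal(size=(n, 5))
    X[:, 0] += 4 * y
    return X, y


class TestRandomSearch:
    def test_single_point_space_returned(self):
        X, y = separable_data()
        space = SearchSpace(spaces={"decision_tree": {"max_depth": [3]}},
                            n_iterations=4, seed=0)
        out = random_search_cv(X, y, "decision_tree", space)
        assert out["best_params"] == {"max_depth": 3}

    def test_best_score_is_trace_max(self):
        X, y = separable_data(seed=1)
        out = random_search_cv(X, y, "random_forest",
                               SearchSpace(n_iterations=6, seed=1))
        assert out["best_score"] == max(t["mean_score"] for t in out["trace"])
        assert len(out["trace"]) == 6

    def test_deeper_tree_dominates_stump_on_structured_data(self):
        # Two informative axes need depth >= 2; the searched depth must
        # score at least as well as a depth-1 stump.
        rng = np.random.default_rng(2)
        n = 120
        a, b = rng.integers(0, 2, n), rng.integers(0, 2, n)
        y = a ^ b
        X = np.column_stack([a + 0.05 * rng.normal(size=n),
                             b + 0.05 * rng.normal(size=n)])
        space = SearchSpace(spaces={"decision_tree":
                                    {"max_depth": list(range(1, 21))}},
                            n_iterations=12, seed=0)
        out = random_search_cv(X, y, "decision_tree", space)
        stump = random_search_cv(X, y, "decision_tree",
                                 SearchSpace(spaces={"decision_tree":
                                                     {"max_depth": [1]}},
                                             n_iterations=1, seed=0))
        assert out["best_score"] >= stump["best_score"]

    def test_unknown_method_lists_supported(self):
        X, y = separable_data()
        with pytest.raises(ValueError, match="random_forest"):
            random_search_cv(X, y, "naive_bayes", SearchSpace())

    def test_seeded_determinism(self):
        X, y = separable_data(seed=3)
        space = SearchSpace(n_iterations=5, seed=7)
        a = random_search_cv(X, y, "svm", space)
        b = random_search_cv(X, y, "svm", space)
        assert a["best_params"] == b["best_params"]
        assert a["trace"] == b["trace"]

    def test_sampled_candidates_inside_envelopes(self):
        from sklearn.model_selection import ParameterSampler

        envelopes = default_search_space(n_features=10)
        for method, dists in envelopes.items():
            for cand in ParameterSampler(dists, n_iter=20, random_state=0):
                if "n_estimators" in cand:
                    assert 1 <= cand["n_estimators"] <= 30
                if "max_depth" in cand and cand["max_depth"] is not None:
                    assert 1 <= cand["max_depth"] <= 20
                if "C" in cand:
                    assert 0.1 <= cand["C"] <= 10.0
                if "n_neighbors" in cand:
                    assert 1 <= cand["n_neighbors"] <= 15
                if method == "mlp":
                    assert 10 <= cand["hidden_layer_sizes"] <= 200
                    assert 1 <= cand["max_iter"] <= 150


class TestEstimators:
    @pytest.mark.parametrize("method", METHODS)
    def test_all_seven_fit_and_score(self, method):
        from cxrfuse.fusion import decision_scores

        X, y = separable_data(seed=4)
        space = SearchSpace(n_iterations=2, seed=0)
        found = random_search_cv(X, y, method, space)
        est = make_estimator(method, found["best_params"], seed=0)
        est.fit(X, y)
        assert est.predict(X).shape == y.shape
        assert decision_scores(est, X).shape == y.shape

    def test_scaler_only_for_distance_based(self):
        from sklearn.pipeline import Pipeline

        assert isinstance(make_estimator("knn", {"n_neighbors": 3}), Pipeline)
        assert not isinstance(
            make_estimator("decision_tree", {"max_depth": 2}), Pipeline)


class TestLeakageGuard:
    def test_canary_feature_does_not_lift_test_accuracy(self):
        # A column equal to the test labels on test rows (constant on
        # train rows) must not change a tree's test predictions: all
        # fitting statistics come from training rows only.
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(5)
        Xtr, ytr = separable_data(80, seed=6)
        Xte, yte = separable_data(40, seed=7)
        canary_tr = np.zeros((80, 1))
        canary_te = yte.reshape(-1, 1).astype(float)
        base = DecisionTreeClassifier(random_state=0).fit(Xtr, ytr)
        with_canary = DecisionTreeClassifier(random_state=0).fit(
            np.hstack([Xtr, canary_tr]), ytr)
        np.testing.assert_array_equal(
            base.predict(Xte),
            with_canary.predict(np.hstack([Xte, canary_te])))
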