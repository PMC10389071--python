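"""Decision-tree subset search: induction oracle, LOO, exhaustive ranking."""

import numpy as np
import pandas as pd
import pytest

import randgen as rg
from randgen.classify import export_tree_dot, ranking_frame


def _table(features: dict, labels) -> pd.DataFrame:
    frame = pd.DataFrame(features)
    frame["group"] = labels
    frame["participant_id"] = [f"P{i}" for i in range(len(frame))]
    return frame


class TestFitTree:
    def test_separable_one_feature_single_threshold(self):
        table = _table({"x": [1.0, 2, 3, 4, 5, 6, 7, 8]},
                       ["A"] * 4 + ["B"] * 4)
        tree = rg.fit_tree(table, ["x"], rg.TreeSpec())
        # greedy Gini on separable 1-D data: one split at 4.5
        assert tree.tree_.node_count == 3
        assert tree.tree_.threshold[0] == pytest.approx(4.5)
        assert list(tree.predict([[1.0], [8.0]])) == ["A", "B"]

    def test_pure_node_no_splits(self):
        table = _table({"x": [1.0, 2, 3, 4, 5, 6, 7, 8]}, ["A"] * 8)
        tree = rg.fit_tree(table, ["x"], rg.TreeSpec())
        assert tree.tree_.node_count == 1
        assert tree.predict([[3.0]])[0] == "A"

    def test_manual_greedy_gini_trace(self):
        """8-row toy table: hand-executed greedy Gini induction.

        Labels A A A B A B B B over x = 1..8. The split x <= 3.5 gives a
        pure left child and weighted Gini 5/8 * 0.32 = 0.2, beating every
        other threshold (x <= 4.5 gives 0.375), so the greedy root picks
        3.5; both children fall below min_samples_split = 7 and become
        majority leaves (A left, B right).
        """
        x = [1.0, 2, 3, 4, 5, 6, 7, 8]
        y = ["A", "A", "A", "B", "A", "B", "B", "B"]
        table = _table({"x": x}, y)
        tree = rg.fit_tree(table, ["x"], rg.TreeSpec())
        assert tree.tree_.node_count == 3
        assert tree.tree_.threshold[0] == pytest.approx(3.5)
        assert list(tree.predict([[2.0], [7.0]])) == ["A", "B"]

    def test_respects_min_samples_split(self):
        # 6 rows < min_samples_split=7: no split despite impurity
        table = _table({"x": [1.0, 2, 3, 4, 5, 6]}, ["A", "A", "A", "B", "B", "B"])
        tree = rg.fit_tree(table, ["x"], rg.TreeSpec())
        assert tree.tree_.node_count == 1


class TestLooAccuracy:
    def test_perfectly_separable_is_one(self):
        table = _table({"x": list(np.linspace(0, 1, 10)) + list(np.linspace(5, 6, 10))},
                       ["A"] * 10 + ["B"] * 10)
        assert rg.loo_accuracy(table, ["x"]).loo_accuracy == 1.0

    def test_constant_feature_hits_loo_majority_pathology(self):
        """An unsplittable feature makes every fold a majority vote, and
        with balanced labels the held-out participant is always in the
        training minority: leave-one-out accuracy is exactly 0, the classic
        LOO majority artifact (not 0.5)."""
        table = _table({"x": np.zeros(38)}, ["A"] * 19 + ["B"] * 19)
        assert rg.loo_accuracy(table, ["x"]).loo_accuracy == 0.0

    def test_label_independent_feature_near_chance(self):
        """A noisy label-independent feature stays near chance on average."""
        rng = np.random.default_rng(0)
        accs = []
        for seed in range(10):
            labels = rng.permutation(["A"] * 19 + ["B"] * 19)
            table = _table({"x": rng.normal(0, 1, 38)}, labels)
            accs.append(
                rg.loo_accuracy(table, ["x"], rg.TreeSpec(seed=seed)).loo_accuracy
            )
        assert 0.25 < float(np.mean(accs)) < 0.75

    def test_per_fold_predictions_complete(self, paper_like_features):
        result = rg.loo_accuracy(paper_like_features, ["FOD_8", "FOD_-8"])
        assert len(result.per_fold_predictions) == len(paper_like_features)
        correct = sum(p == a for _, p, a in result.per_fold_predictions)
        assert result.loo_accuracy == pytest.approx(
            correct / len(paper_like_features)
        )

    def test_monotone_transform_invariance(self, paper_like_features):
        """Axis-aligned thresholds only use feature order."""
        table = paper_like_features[["participant_id", "group", "FOD_1", "Cf"]].copy()
        transformed = table.copy()
        transformed["FOD_1"] = np.exp(transformed["FOD_1"] / 10.0)
        transformed["Cf"] = transformed["Cf"] ** 3
        a = rg.loo_accuracy(table, ["FOD_1", "Cf"])
        b = rg.loo_accuracy(transformed, ["FOD_1", "Cf"])
        assert a.loo_accuracy == pytest.approx(b.loo_accuracy)


class TestExhaustiveSearch:
    @pytest.fixture(scope="class")
    def ten_feature_table(self):
        rng = np.random.default_rng(17)
        labels = ["A"] * 20 + ["B"] * 20
        features = {f"f{i}": rng.normal(0, 1, 40) for i in range(9)}
        # one informative feature: clean 2-sd separation
        features["signal"] = np.r_[rng.normal(0, 1, 20), rng.normal(4, 1, 20)]
        return _table(features, labels)

    def test_subset_count_ten_features(self, ten_feature_table):
        results = rg.exhaustive_search(ten_feature_table, max_subset_size=3)
        assert len(results) == 10 + 45 + 120

    def test_single_feature_single_subset(self):
        table = _table({"x": np.r_[np.zeros(5), np.ones(5)]}, ["A"] * 5 + ["B"] * 5)
        assert len(rg.exhaustive_search(table, max_subset_size=3)) == 1

    def test_informative_feature_tops_ranking(self, ten_feature_table):
        results = rg.exhaustive_search(ten_feature_table, max_subset_size=2)
        assert "signal" in results[0].feature_subset

    def test_deterministic_ranking(self, ten_feature_table):
        first = rg.exhaustive_search(ten_feature_table, max_subset_size=2)
        second = rg.exhaustive_search(ten_feature_table, max_subset_size=2)
        assert [r.feature_subset for r in first] == [r.feature_subset for r in second]
        assert [r.loo_accuracy for r in first] == [r.loo_accuracy for r in second]

    def test_tie_break_smaller_subset_then_lexicographic(self):
        table = _table(
            {"a": np.r_[np.zeros(10), np.ones(10)],
             "b": np.r_[np.zeros(10), np.ones(10)]},
            ["A"] * 10 + ["B"] * 10,
        )
        results = rg.exhaustive_search(table, max_subset_size=2)
        assert [r.feature_subset for r in results] == [("a",), ("b",), ("a", "b")]

    def test_budget_guard(self, ten_feature_table):
        with pytest.raises(ValueError, match="budget"):
            rg.exhaustive_search(ten_feature_table, max_subset_size=3, budget=10)

    def test_missing_value_feature_excluded(self):
        rng = np.random.default_rng(1)
        table = _table(
            {"ok": rng.normal(0, 1, 12), "bad": [np.nan] + [1.0] * 11},
            ["A"] * 6 + ["B"] * 6,
        )
        results = rg.exhaustive_search(table, max_subset_size=1)
        assert [r.feature_subset for r in results] == [("ok",)]

    def test_ranking_frame_and_dot_export(self, ten_feature_table):
        results = rg.exhaustive_search(ten_feature_table, max_subset_size=1)
        frame = ranking_frame(results)
        assert list(frame.columns) == ["rank", "features", "k", "loo_accuracy"]
        dot = export_tree_dot(ten_feature_table, results[0].feature_subset)
        assert dot.startswith("digraph")
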