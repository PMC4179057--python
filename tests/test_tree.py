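"""C4.5 tree: entropy arithmetic, split selection, prediction, cross-validation."""

import math

import numpy as np
import pandas as pd
import pytest

from nightwatch.features import build_dataset
from nightwatch.simulator import ScenarioConfig, simulate
from nightwatch.tree import (
    candidate_splits,
    categorical_split_score,
    cross_validate,
    entropy,
    select_split,
    stratified_folds,
    train_c45,
)


def toy_table():
    """Six rows, three positive / three negative: H(3+,3-) = 1 bit."""
    return pd.DataFrame({
        "colour": ["a", "a", "a", "b", "b", "b"],
        "size": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "label": ["+", "+", "-", "+", "-", "-"],
    })


class TestEntropyArithmetic:
    def test_balanced_binary_entropy_is_one_bit(self):
        assert entropy(["+", "+", "+", "-", "-", "-"]) == pytest.approx(1.0)

    def test_gain_ratio_matches_hand_computation_on_toy_table(self):
        """colour splits 6 rows into (2+,1-) and (1+,2-):
        children entropy H = -(2/3)log2(2/3) - (1/3)log2(1/3) each,
        gain = 1 - H, split info = 1 bit, so gain ratio = gain."""
        df = toy_table()
        cand = categorical_split_score(df["colour"], df["label"])
        h_child = -(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3)
        expected_gain = 1.0 - h_child
        assert cand.gain == pytest.approx(expected_gain, rel=1e-12)
        assert cand.gain_ratio == pytest.approx(expected_gain, rel=1e-12)

    def test_numeric_candidate_threshold_at_midpoint(self):
        df = toy_table()
        cands = candidate_splits(df[["size"]], df["label"], [], ["size"],
                                 min_leaf=1)
        assert len(cands) == 1
        # best cut separates {1,2,3,4} from {5,6}? verify against exhaustive scan
        best = cands[0]
        sv = df["size"].to_numpy()
        labels = df["label"].to_numpy(dtype=object)
        h_parent = entropy(labels)
        scores = {}
        for i in range(5):
            t = (sv[i] + sv[i + 1]) / 2
            left = labels[sv <= t]
            right = labels[sv > t]
            w = len(left) / 6
            h = w * entropy(left) + (1 - w) * entropy(right)
            si = -w * math.log2(w) - (1 - w) * math.log2(1 - w)
            scores[t] = (h_parent - h) / si
        top = max(scores.values())
        t_best = min(t for t, s in scores.items() if s >= top - 1e-12)
        assert best.threshold == pytest.approx(t_best)   # smaller threshold on ties
        assert best.gain_ratio == pytest.approx(scores[t_best], rel=1e-12)


class TestSplitSelection:
    def test_chosen_split_maximizes_gain_ratio_under_mean_gain_filter(self):
        """Exhaustive node-level re-scan on a small mixed-type dataset."""
        rng = np.random.default_rng(0)
        n = 60
        df = pd.DataFrame({
            "cat": rng.choice(["x", "y", "z"], n),
            "num1": rng.normal(size=n),
            "num2": rng.normal(size=n),
        })
        labels = np.where((df["cat"] == "x") | (df["num1"] > 0.3), "p", "q")
        cands = candidate_splits(df, labels, ["cat"], ["num1", "num2"], min_leaf=2)
        chosen = select_split(cands)
        pos = [c for c in cands if c.gain > 1e-12]
        mean_gain = sum(c.gain for c in pos) / len(pos)
        eligible = [c for c in pos if c.gain >= mean_gain - 1e-12]
        assert chosen in eligible
        assert all(chosen.gain_ratio >= c.gain_ratio - 1e-12 for c in eligible)

    def test_no_positive_gain_returns_none(self):
        df = pd.DataFrame({"num": [1.0, 2.0, 1.0, 2.0]})
        labels = np.array(["a", "a", "b", "b"], dtype=object)  # num uninformative
        # both values hold one 'a' and one 'b': zero information gain
        cands = candidate_splits(df, labels, [], ["num"], min_leaf=1)
        assert select_split(cands) is None


class TestTrainedTree:
    def test_perfect_categorical_attribute_gives_depth_one_tree(self):
        df = pd.DataFrame({
            "room": ["K", "K", "K", "Ba", "Ba", "Ba"] * 3,
            "noise": list(np.linspace(0, 1, 18)),
            "label": ["TPI", "TPI", "TPI", "!TPI", "!TPI", "!TPI"] * 3,
        })
        tree = train_c45(df, categorical=["room"], numeric=["noise"],
                         min_leaf=1, max_depth=10)
        assert tree.depth == 1
        assert tree.root.attr == "room"
        assert tree.predict(df) == list(df["label"])

    def test_single_class_data_gives_single_leaf(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "label": ["a", "a", "a"]})
        tree = train_c45(df, categorical=[], numeric=["x"])
        assert tree.root.is_leaf and tree.root.label == "a"

    def test_training_observations_reach_their_training_leaf_label(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "c": rng.choice(["u", "v"], 80),
            "x": rng.normal(size=80),
        })
        df["label"] = np.where(df["c"] == "u", "p", "q")
        tree = train_c45(df, categorical=["c"], numeric=["x"], min_leaf=5)
        assert tree.predict(df) == list(df["label"])

    def test_unseen_categorical_value_routes_to_majority_child(self):
        df = pd.DataFrame({
            "c": ["u"] * 12 + ["v"] * 4,
            "label": ["p"] * 12 + ["q"] * 4,
        })
        tree = train_c45(df, categorical=["c"], numeric=[], min_leaf=2)
        assert not tree.root.is_leaf
        unseen = pd.DataFrame({"c": ["w"]})
        # majority child is the u-branch (12 of 16 samples) labeled p
        assert tree.predict(unseen) == ["p"]

    def test_observation_order_does_not_change_tree(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "c": rng.choice(["u", "v", "w"], 100),
            "x": rng.normal(size=100),
            "label": rng.choice(["p", "q"], 100),
        })
        t1 = train_c45(df, categorical=["c"], numeric=["x"])
        shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
        t2 = train_c45(shuffled, categorical=["c"], numeric=["x"])
        assert t1.to_text() == t2.to_text()

    def test_missing_feature_column_rejected(self):
        df = pd.DataFrame({"x": [0.0, 1.0] * 6, "label": ["a", "b"] * 6})
        tree = train_c45(df, categorical=[], numeric=["x"], min_leaf=1)
        with pytest.raises(ValueError, match="missing"):
            tree.predict(pd.DataFrame({"y": [1.0]}))

    def test_planted_kitchen_structure_recovered_near_root(self):
        """Kitchen/living-room activity planted only before midnight should
        drive the first splits of the early-night model."""
        cfg = ScenarioConfig(seed=6, n_nights=14)
        recs = simulate(cfg, include_loadcell=False)
        ds = build_dataset({r.night_id: r.events_with_true_bed() for r in recs},
                           {r.night_id: r.night_start for r in recs})
        tree = train_c45(ds)
        top = {tree.root.attr} | {c.attr for c in tree.root.children.values()
                                  if not c.is_leaf}
        assert top & {"n_K", "n_L", "ev_t", "ev_t1"}


class TestCrossValidation:
    def test_folds_partition_dataset_with_balanced_sizes(self):
        labels = np.array(["a"] * 37 + ["b"] * 13, dtype=object)
        folds = stratified_folds(labels, k=10, seed=0)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(50))
        sizes = [len(f) for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_fold_assignment_reproducible_from_seed(self):
        labels = np.array(["a", "b"] * 30, dtype=object)
        f1 = stratified_folds(labels, k=5, seed=9)
        f2 = stratified_folds(labels, k=5, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array(["a", "b"], dtype=object), k=3, seed=0)

    def test_perfectly_separable_dataset_scores_one(self):
        df = pd.DataFrame({
            "c": ["u", "v"] * 50,
            "label": ["p", "q"] * 50,
        })
        cv = cross_validate(df, k=10, seed=1, categorical=["c"], numeric=[],
                            min_leaf=2)
        assert cv["mean_accuracy"] == pytest.approx(1.0)

    def test_shuffled_labels_score_near_majority_baseline(self):
        rng = np.random.default_rng(3)
        n = 200
        df = pd.DataFrame({
            "c": rng.choice(["u", "v", "w"], n),
            "x": rng.normal(size=n),
            "label": rng.permutation(["p"] * 150 + ["q"] * 50),
        })
        cv = cross_validate(df, k=10, seed=3, categorical=["c"], numeric=["x"])
        assert abs(cv["mean_accuracy"] - cv["majority_baseline"]) <= 0.1

    def test_matches_sklearn_tree_on_separable_numeric_data(self):
        """Cross-check against an independent tree learner on data where
        both should find the same decision boundary."""
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-2, 0.5, 100), rng.normal(2, 0.5, 100)])
        df = pd.DataFrame({"x": x, "label": ["p"] * 100 + ["q"] * 100})
        ours = train_c45(df, categorical=[], numeric=["x"], min_leaf=5)
        clf = sklearn_tree.DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=5, random_state=0)
        clf.fit(df[["x"]], df["label"])
        grid = pd.DataFrame({"x": np.linspace(-4, 4, 201)})
        agree = np.mean(np.asarray(ours.predict(grid), dtype=object)
                        == clf.predict(grid[["x"]]))
        assert agree >= 0.98
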