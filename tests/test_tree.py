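import numpy as np
import pytest

from epiclass import TreeParams, forest_importance, gini, train_tree
from epiclass.tree import (
    TreeNode,
    best_split,
    load_tree,
    predict,
    predict_proba,
    save_tree,
    tree_from_dict,
    tree_to_dict,
)


def brute_force_best_split(X, y, min_leaf):
    """Exhaustive search over all (attribute, midpoint-threshold) splits."""
    n = len(y)
    parent = gini((y.sum(), n - y.sum()))
    best = None
    for j in range(X.shape[1]):
        values = np.unique(X[:, j])
        for a, b in zip(values, values[1:]):
            thr = (a + b) / 2
            left = X[:, j] <= thr
            nl, nr = left.sum(), n - left.sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            g = (
                nl * gini((y[left].sum(), nl - y[left].sum()))
                + nr * gini((y[~left].sum(), nr - y[~left].sum()))
            ) / n
            cand = (-(parent - g), j, thr)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    return best[1], best[2], -best[0]


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected",
        [((10, 0), 0.0), ((5, 5), 0.5), ((3, 1), 0.375), ((0, 7), 0.0)],
    )
    def test_closed_forms(self, counts, expected):
        assert gini(counts) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini((0, 0))


class TestTraining:
    def test_separable_one_dimensional(self):
        X = np.array([[-2.0], [-1.0], [-0.5], [1.5], [2.0], [3.0]])
        y = np.array([True, True, True, False, False, False])
        t = train_tree(X, y, ["x"], TreeParams(max_depth=3, min_leaf=1, min_split=2))
        assert (predict(t, X) == y).all()
        assert t.left.is_leaf and t.right.is_leaf  # a single split suffices

    def test_xor_needs_depth_two(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]] * 3)
        y = np.array([False, True, True, False] * 3)
        deep = train_tree(X, y, ["a", "b"], TreeParams(max_depth=2, min_leaf=1, min_split=2))
        assert (predict(deep, X) == y).all()
        shallow = train_tree(X, y, ["a", "b"], TreeParams(max_depth=1, min_leaf=1, min_split=2))
        assert np.mean(predict(shallow, X) == y) <= 0.75

    def test_determinism(self, rng):
        X = rng.normal(size=(80, 5))
        y = X[:, 2] + 0.3 * rng.normal(size=80) > 0
        t1 = train_tree(X, y, list("abcde"))
        t2 = train_tree(X, y, list("abcde"))
        assert tree_to_dict(t1) == tree_to_dict(t2)

    def test_single_class_warns_and_leafs(self):
        X = np.zeros((5, 2))
        with pytest.warns(UserWarning, match="single-class"):
            t = train_tree(X, np.ones(5, dtype=bool), ["a", "b"])
        assert t.is_leaf and t.probability == 1.0

    def test_class_counts_conserved_and_decrease_nonnegative(self, rng):
        X = rng.normal(size=(200, 4))
        y = X[:, 0] > 0.2
        t = train_tree(X, y, list("abcd"))

        def walk(node):
            if node.is_leaf:
                return
            le, ri = node.left, node.right
            assert (
                node.class_counts[0] == le.class_counts[0] + ri.class_counts[0]
                and node.class_counts[1] == le.class_counts[1] + ri.class_counts[1]
            )
            n = sum(node.class_counts)
            dec = gini(node.class_counts) - (
                sum(le.class_counts) * gini(le.class_counts)
                + sum(ri.class_counts) * gini(ri.class_counts)
            ) / n
            assert dec >= -1e-12
            walk(le)
            walk(ri)

        walk(t)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search_on_small_instances(self, seed):
        """Recursively, every chosen split equals the brute-force optimum."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        X = np.round(rng.normal(size=(n, 2)), 2)
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            y[0] = not y[0]
        params = TreeParams(max_depth=4, min_leaf=1, min_split=2)
        t = train_tree(X, y, ["a", "b"], params)

        def check(node, idx):
            sub_X, sub_y = X[idx], y[idx]
            if (
                node.depth >= params.max_depth
                or len(idx) < params.min_split
                or sub_y.all()
                or not sub_y.any()
            ):
                assert node.is_leaf
                return
            expected = brute_force_best_split(sub_X, sub_y, params.min_leaf)
            got = best_split(sub_X, sub_y, params.min_leaf)
            if expected is None:
                assert got is None and node.is_leaf
                return
            assert got is not None and not node.is_leaf
            assert node.attr_index == expected[0]
            assert node.threshold == pytest.approx(expected[1])
            assert got[2] == pytest.approx(expected[2])
            mask = sub_X[:, node.attr_index] <= node.threshold
            check(node.left, idx[mask])
            check(node.right, idx[~mask])

        check(t, np.arange(n))

    def test_training_accuracy_matches_sklearn(self, rng):
        """Independent CART implementation reaches the same training accuracy."""
        from sklearn.tree import DecisionTreeClassifier

        X = rng.normal(size=(300, 6))
        y = (X[:, 0] + X[:, 3] ** 2) > 0.5
        params = TreeParams(max_depth=5, min_leaf=5, min_split=10)
        mine = train_tree(X, y, list("abcdef"), params)
        sk = DecisionTreeClassifier(
            max_depth=5, min_samples_leaf=5, min_samples_split=10, random_state=0
        ).fit(X, y)
        acc_mine = np.mean(predict(mine, X) == y)
        acc_sk = sk.score(X, y)
        assert acc_mine == pytest.approx(acc_sk, abs=0.02)


class TestPrediction:
    def test_leaf_fraction_scores(self):
        leaf = TreeNode(class_counts=(49, 51), depth=0)
        assert predict_proba(leaf, np.zeros((3, 2))) == pytest.approx([0.49] * 3)
        pure = TreeNode(class_counts=(10, 0), depth=0)
        assert predict_proba(pure, np.zeros((1, 2)))[0] == 1.0

    def test_piecewise_constant(self, rng):
        X = rng.normal(size=(50, 3))
        y = X[:, 1] > 0
        t = train_tree(X, y, list("abc"), TreeParams(max_depth=2, min_leaf=5, min_split=10))
        a = predict_proba(t, np.array([[0.0, -5.0, 0.0]]))[0]
        b = predict_proba(t, np.array([[9.9, -5.0, -9.9]]))[0]
        if t.split_attribute == "b":  # same leaf when only the split attr matters
            assert a == b


class TestSerialization:
    def test_bit_exact_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(120, 4))
        y = X[:, 0] * X[:, 1] > 0
        t = train_tree(X, y, list("abcd"))
        p = tmp_path / "model.json"
        save_tree(p, t, {"note": "test"})
        back, meta = load_tree(p)
        assert tree_to_dict(back) == tree_to_dict(t)
        assert meta["note"] == "test"
        # identical predictions, bit for bit
        np.testing.assert_array_equal(predict_proba(back, X), predict_proba(t, X))

    def test_dict_round_trip(self):
        t = TreeNode(
            class_counts=(3, 4),
            depth=0,
            split_attribute="a",
            attr_index=0,
            threshold=0.123456789,
            left=TreeNode((3, 0), 1),
            right=TreeNode((0, 4), 1),
        )
        assert tree_to_dict(tree_from_dict(tree_to_dict(t))) == tree_to_dict(t)

    def test_wrong_file_rejected(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"model": "other"}')
        with pytest.raises(ValueError):
            load_tree(p)


class TestForestImportance:
    def test_planted_signal_ranks_first(self, rng):
        X = rng.normal(size=(200, 5))
        y = X[:, 2] > 0.0
        imp = forest_importance(X, y, list("abcde"), n_trees=30, seed=0)
        assert imp["decreased_gini"].idxmax() == "c"
        assert imp["decreased_accuracy"].idxmax() == "c"

    def test_noise_attributes_near_zero_accuracy_drop(self, rng):
        X = rng.normal(size=(150, 4))
        y = X[:, 0] > 0
        imp = forest_importance(X, y, list("abcd"), n_trees=40, seed=1)
        noise = imp.loc[["b", "c", "d"], "decreased_accuracy"]
        assert (noise.abs() < 0.05).all()

    def test_single_tree_degenerate_ensemble(self, rng):
        X = rng.normal(size=(60, 3))
        y = X[:, 1] > 0
        imp = forest_importance(X, y, list("abc"), n_trees=1, seed=5)
        assert (imp["decreased_gini"] >= 0).all()
        assert imp.shape == (3, 2)

    def test_invalid_n_trees(self, rng):
        with pytest.raises(ValueError):
            forest_importance(np.zeros((4, 2)), np.array([1, 0, 1, 0], bool), ["a", "b"], 0)
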