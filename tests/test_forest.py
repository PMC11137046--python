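import numpy as np
import pytest
from sklearn.tree import DecisionTreeRegressor

from sauroncp import (ForestParams, ResponseBundle, SampleWeights, SauronForest,
                      compute_sample_weights, fit_forest, forest_predict,
                      forest_sample_weights, predict_quantile, tree_predict)
from sauroncp.forest import _Tree, _build_tree


# ---------------------------------------------------------------- helpers


def single_leaf_tree(member_ids, member_w, value, mode):
    """A hand-built stump whose only node is a leaf."""
    return _Tree(
        children_left=np.array([-1]), children_right=np.array([-1]),
        feature=np.array([-2]), threshold=np.array([-2.0]),
        leaf_slot=np.array([0]), leaf_start=np.array([0, len(member_ids)]),
        member_ids=np.asarray(member_ids), member_w=np.asarray(member_w, float),
        leaf_value=np.array([float(value)]), leaf_mode=np.array([mode]))


def stump_forest(trees, y_train, class_labels=(0, 1), modal_class=0, p=2):
    return SauronForest(trees, np.asarray(y_train, float), class_labels,
                        modal_class, ForestParams(n_trees=len(trees)), p)


def brute_force_qrf(forest, X_boot_leaves, x, level):
    """Meinshausen-style quantile from naively recomputed weights."""
    w = brute_force_weights_via_members(forest, X_boot_leaves, x)
    order = np.argsort(forest.y_train)
    cum = 0.0
    for i in order:
        cum += w[i]
        if cum >= level - 1e-12:
            return forest.y_train[i]
    return forest.y_train[order[-1]]


def brute_force_weights_via_members(forest, boot_leaves, x):
    """w_i(x) recomputed by explicit loops from the stored bootstraps and the
    raw w* weights; tree routing done by naive traversal."""
    N = len(forest.y_train)
    B = forest.n_trees
    leaves, votes = [], []
    for t in forest.trees:
        node = 0
        while t.children_left[node] != -1:
            node = (t.children_left[node] if x[t.feature[node]] <= t.threshold[node]
                    else t.children_right[node])
        slot = int(t.leaf_slot[node])
        leaves.append(slot)
        votes.append(int(t.leaf_mode[slot]))
    counts = {c: votes.count(c) for c in forest.class_labels}
    best = max(counts.values())
    point_class = min(c for c in counts if counts[c] == best)
    if point_class == forest.modal_class:
        tw = [1.0 / B] * B
    else:
        agree = [v == point_class for v in votes]
        tw = [a / sum(agree) for a in agree]
    w = np.zeros(N)
    for b in range(B):
        boot = forest.bootstraps[b]
        in_leaf = boot[boot_leaves[b] == leaves[b]]
        total = float(np.sum(forest.w_star[in_leaf]))
        for m in in_leaf:
            w[m] += tw[b] * forest.w_star[m] / total
    return w


def boot_leaf_slots(forest, X):
    """Leaf slot of every bootstrap row, per tree (for the oracles)."""
    out = []
    for b, t in enumerate(forest.trees):
        out.append(t.apply(X[forest.bootstraps[b]]))
    return out


# ------------------------------------------------------------- leaf formula


class TestLeafAveraging:
    def test_weighted_leaf_value_and_normalization(self):
        # leaf members with w* = (1, 3) and y = (0, 4): normalized weights
        # (0.25, 0.75), prediction 3.0
        X = np.zeros((2, 1))
        y = np.array([0.0, 4.0])
        dt = DecisionTreeRegressor(max_features=1, min_samples_leaf=1)
        dt.fit(X, y, sample_weight=np.array([1.0, 3.0]))
        tree = _build_tree(dt, X, y, np.array([0, 1]), np.array([1.0, 3.0]),
                           boot=np.array([0, 1]), labels_sorted=np.array([0, 1]))
        assert tree.leaf_value[0] == pytest.approx(3.0)
        assert np.allclose(np.sort(tree.member_w), [0.25, 0.75])

    def test_equal_weights_take_plain_mean(self):
        X = np.zeros((2, 1))
        y = np.array([1.0, 3.0])
        dt = DecisionTreeRegressor(min_samples_leaf=1).fit(
            X, y, sample_weight=np.ones(2))
        tree = _build_tree(dt, X, y, np.array([0, 1]), np.ones(2),
                           boot=np.array([0, 1]), labels_sorted=np.array([0, 1]))
        assert tree.leaf_value[0] == pytest.approx(2.0)

    def test_bootstrap_duplicates_aggregate_onto_original_id(self):
        X = np.zeros((3, 1))
        y = np.array([1.0, 2.0, 9.0])
        boot = np.array([0, 0, 1])  # sample 0 drawn twice
        dt = DecisionTreeRegressor(min_samples_leaf=1).fit(
            X[boot], y[boot], sample_weight=np.ones(3))
        tree = _build_tree(dt, X, y, np.array([0, 0, 1]), np.ones(3),
                           boot=boot, labels_sorted=np.array([0, 1]))
        assert set(tree.member_ids.tolist()) == {0, 1}
        w = dict(zip(tree.member_ids.tolist(), tree.member_w.tolist()))
        assert w[0] == pytest.approx(2 / 3)
        assert w[1] == pytest.approx(1 / 3)


class TestTreePredict:
    def test_single_member_leaf_returns_its_response(self):
        t = single_leaf_tree([2], [1.0], 5.5, 0)
        f = stump_forest([t], [0.0, 1.0, 5.5])
        assert tree_predict(f, 0, np.zeros(2)) == 5.5

    def test_invalid_tree_id(self, small_forest):
        with pytest.raises(IndexError):
            tree_predict(small_forest, small_forest.n_trees, np.zeros(6))


# ------------------------------------------------------- forest aggregation


class TestForestVote:
    def test_unanimous_vote(self):
        trees = [single_leaf_tree([0], [1.0], 1.0, 1) for _ in range(4)]
        f = stump_forest(trees, [1.0], modal_class=0)
        p = forest_predict(f, np.zeros(2))
        assert p.point_class == 1
        assert p.vote(1) == 1.0
        # non-modal prediction: all trees agree -> each weighted 1/4
        assert np.allclose(p.tree_weights, 0.25)

    def test_tie_breaks_to_lower_label(self):
        trees = ([single_leaf_tree([0], [1.0], 1.0, 1)] * 2
                 + [single_leaf_tree([0], [1.0], 2.0, 0)] * 2)
        f = stump_forest(trees, [1.0], modal_class=0)
        assert forest_predict(f, np.zeros(2)).point_class == 0

    def test_minority_prediction_downweights_disagreeing_trees(self):
        # 2 trees vote the non-modal class (values 1.0 and 2.0), one tree
        # disagrees (9.0): prediction is (1+2)/2 = 1.5
        trees = [single_leaf_tree([0], [1.0], 1.0, 1),
                 single_leaf_tree([0], [1.0], 2.0, 1),
                 single_leaf_tree([0], [1.0], 9.0, 0)]
        f = stump_forest(trees, [1.0], modal_class=0)
        p = forest_predict(f, np.zeros(2))
        assert p.point_class == 1
        assert p.point_value == pytest.approx(1.5)
        assert np.allclose(p.tree_weights, [0.5, 0.5, 0.0])

    def test_modal_prediction_uses_all_trees(self):
        trees = [single_leaf_tree([0], [1.0], 1.0, 0),
                 single_leaf_tree([0], [1.0], 2.0, 0),
                 single_leaf_tree([0], [1.0], 9.0, 1)]
        f = stump_forest(trees, [1.0], modal_class=0)
        p = forest_predict(f, np.zeros(2))
        assert p.point_class == 0
        assert p.point_value == pytest.approx((1.0 + 2.0 + 9.0) / 3)


class TestQuantiles:
    def test_uniform_weights_median(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        t = single_leaf_tree([0, 1, 2, 3], [0.25] * 4, 2.5, 0)
        f = stump_forest([t], y)
        assert predict_quantile(f, np.zeros(2), 0.5) == 2.0
        assert predict_quantile(f, np.zeros(2), 1.0) == 4.0
        assert predict_quantile(f, np.zeros(2), 0.25) == 1.0

    def test_point_mass(self):
        t = single_leaf_tree([1], [1.0], 7.0, 0)
        f = stump_forest([t], [0.0, 7.0, 9.0])
        for level in (0.01, 0.5, 1.0):
            assert predict_quantile(f, np.zeros(2), level) == 7.0

    def test_invalid_level(self, small_forest):
        with pytest.raises(ValueError):
            predict_quantile(small_forest, np.zeros(6), 0.0)

    def test_nondecreasing_in_level(self, small_forest, small_dataset):
        fm, _, _ = small_dataset
        levels = np.linspace(0.05, 1.0, 20)
        q = small_forest.predict_quantile(fm.values[:5], levels)
        assert np.all(np.diff(q, axis=1) >= -1e-12)

    def test_cdf_is_monotone_and_reaches_one(self, small_forest, small_dataset):
        fm, _, _ = small_dataset
        cdf = small_forest.conditional_cdf(fm.values[3])
        assert np.all(np.diff(cdf.cdf) >= -1e-12)
        assert cdf.cdf[-1] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(cdf.support) > 0)


# ------------------------------------------------------- fitting behaviour


class TestFitting:
    def test_constant_response_predicts_constant(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 3))
        y = np.full(30, 2.5)
        d = np.array([0, 1] * 15)
        bundle = ResponseBundle(y, d, (1, 0))
        f = fit_forest(X, bundle, SampleWeights(np.ones(30), "simple"),
                       ForestParams(n_trees=5, min_leaf=2, seed=1))
        vals, _, _, _ = f.predict_batch(rng.standard_normal((10, 3)))
        assert np.allclose(vals, 2.5)

    def test_separated_clusters_reach_zero_training_error(self):
        # two clusters in one feature with distinct responses: every leaf pure
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(5, 6, 20)])
        y = np.concatenate([np.full(20, 1.0), np.full(20, 3.0)])
        bundle = ResponseBundle.from_continuous(y, [2.0])
        f = fit_forest(x[:, None], bundle, SampleWeights(np.ones(40), "simple"),
                       ForestParams(n_trees=10, min_leaf=1, seed=2))
        vals, classes, _, _ = f.predict_batch(x[:, None])
        assert np.mean((vals - y) ** 2) == pytest.approx(0.0, abs=1e-12)
        assert np.array_equal(classes, bundle.d)

    def test_too_few_samples_raises(self):
        bundle = ResponseBundle(np.array([1.0, 2.0]), np.array([0, 1]), (1, 0))
        with pytest.raises(ValueError):
            fit_forest(np.zeros((2, 1)), bundle, SampleWeights(np.ones(2), "simple"),
                       ForestParams(min_leaf=5))

    def test_non_finite_inputs_raise(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        bundle = ResponseBundle(y, np.array([1, 1, 0, 0]), (1, 0))
        X = np.zeros((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_forest(X, bundle, SampleWeights(np.ones(4), "simple"),
                       ForestParams(min_leaf=1))

    def test_fixed_seed_reproducible(self, small_dataset):
        fm, bundle, _ = small_dataset
        w = compute_sample_weights(bundle, "simple")
        params = ForestParams(n_trees=6, min_leaf=3, seed=42)
        f1 = fit_forest(fm, bundle, w, params)
        f2 = fit_forest(fm, bundle, w, params)
        q = np.linspace(0.1, 0.9, 5)
        assert np.array_equal(f1.predict_quantile(fm.values[:7], q),
                              f2.predict_quantile(fm.values[:7], q))
        v1, c1, _, _ = f1.predict_batch(fm.values)
        v2, c2, _, _ = f2.predict_batch(fm.values)
        assert np.array_equal(v1, v2) and np.array_equal(c1, c2)


# ------------------------------------------------------------- invariants


class TestNormalizationInvariants:
    def test_leaf_weights_sum_to_one(self, small_forest):
        for t in small_forest.trees:
            for s in range(len(t.leaf_value)):
                w = t.member_w[t.leaf_start[s]:t.leaf_start[s + 1]]
                assert abs(w.sum() - 1.0) < 1e-10

    def test_tree_and_forest_weights_sum_to_one(self, small_forest, small_dataset):
        fm, _, _ = small_dataset
        rng = np.random.default_rng(3)
        Xq = rng.standard_normal((25, fm.n_features))
        _, _, _, tw = small_forest.predict_batch(Xq)
        assert np.allclose(tw.sum(axis=0), 1.0, atol=1e-10)
        W = small_forest.sample_weights(Xq)
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-10)

    def test_tree_average_equals_sample_weight_form(self, small_forest, small_dataset):
        # the per-tree weighted average and the training-sample weighted sum
        # are algebraically identical
        fm, _, _ = small_dataset
        rng = np.random.default_rng(4)
        Xq = rng.standard_normal((100, fm.n_features))
        vals, _, _, _ = small_forest.predict_batch(Xq)
        W = small_forest.sample_weights(Xq)
        assert np.allclose(W @ small_forest.y_train, vals, atol=1e-8)


class TestBruteForceOracle:
    def test_sample_weights_match_naive_recomputation(self, small_forest, small_dataset):
        fm, _, _ = small_dataset
        boot_leaves = boot_leaf_slots(small_forest, fm.values)
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = rng.standard_normal(fm.n_features)
            expected = brute_force_weights_via_members(small_forest, boot_leaves, x)
            got = forest_sample_weights(small_forest, x)
            assert np.allclose(got, expected, atol=1e-12)

    def test_uniform_weight_quantiles_match_qrf_reimplementation(self, small_dataset):
        # balanced classes + simple scheme -> all w* = 1: quantiles equal a
        # naive Meinshausen quantile-regression-forest computation
        rng = np.random.default_rng(6)
        n = 50
        X = rng.standard_normal((n, 4))
        y = rng.standard_normal(n)
        t = float(np.median(y))
        bundle = ResponseBundle.from_continuous(y, [t])
        w = compute_sample_weights(bundle, "simple")
        assert np.allclose(w.w_star, 1.0)
        f = fit_forest(X, bundle, w, ForestParams(n_trees=10, min_leaf=2, seed=9),
                       store_bootstraps=True)
        boot_leaves = boot_leaf_slots(f, X)
        for _ in range(10):
            x = rng.standard_normal(4)
            for level in (0.1, 0.5, 0.9):
                expected = brute_force_qrf(f, boot_leaves, x, level)
                assert f.predict_quantile(x, level) == pytest.approx(expected, abs=1e-8)


class TestSerialization:
    def test_save_load_bit_exact(self, small_forest, small_dataset, tmp_path):
        fm, _, _ = small_dataset
        path = tmp_path / "forest.json"
        small_forest.save(path)
        loaded = SauronForest.load(path)
        rng = np.random.default_rng(8)
        Xq = rng.standard_normal((20, fm.n_features))
        v1, c1, p1, _ = small_forest.predict_batch(Xq)
        v2, c2, p2, _ = loaded.predict_batch(Xq)
        assert np.array_equal(v1, v2)
        assert np.array_equal(c1, c2)
        assert np.array_equal(p1, p2)
        q1 = small_forest.predict_quantile(Xq, [0.05, 0.95])
        q2 = loaded.predict_quantile(Xq, [0.05, 0.95])
        assert np.array_equal(q1, q2)
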