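"""Simultaneous regression + classification random forest (SAURON-RF).

A SAURON forest is a weighted regression random forest whose leaves
additionally carry the discrete class labels of their training members.
Each tree therefore produces both a continuous prediction (the w*-weighted
mean of the responses in the reached leaf) and a class vote (the leaf's
modal class).  The forest classifies by plurality vote over trees, and its
regression prediction is a class-aware weighted average over trees: when the
predicted class is the training modal class, all trees contribute 1/B;
otherwise only the trees agreeing with the forest vote contribute, with
equal weight.

The same machinery yields a quantile-regression extension: expressing the
forest prediction as a weighted sum over *training samples* (tree weights
times per-leaf normalized sample weights, with bootstrap duplicates
aggregated onto their original sample) gives an estimate of the conditional
distribution function F(y | X = x), which is inverted for conditional
quantiles.

Individual trees are grown greedily on bootstrap samples of size N, choosing
at each node the best split among ``max_features`` randomly drawn features
by improvement in w*-weighted mean squared error; tree growth delegates to
scikit-learn's CART implementation, after which the tree structure is copied
into plain arrays so that prediction and (de)serialization are
self-contained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .data import FeatureMatrix, ResponseBundle
from .weights import SampleWeights

__all__ = [
    "ForestParams",
    "SauronForest",
    "ForestPrediction",
    "ConditionalCDF",
    "fit_forest",
    "tree_predict",
    "forest_predict",
    "forest_sample_weights",
    "predict_quantile",
]


@dataclass
class ForestParams:
    """Hyper-parameters of the forest.

    ``max_features`` defaults to ceil(P/3) (regression-forest convention),
    ``min_leaf`` is the minimum number of bootstrap members per leaf, and
    ``seed`` deterministically derives per-tree bootstrap and
    feature-sampling streams.
    """

    n_trees: int = 100
    max_features: int | None = None
    min_leaf: int = 5
    seed: int = 0

    def resolve_max_features(self, n_features: int) -> int:
        m = self.max_features if self.max_features is not None else int(np.ceil(n_features / 3))
        if not 1 <= m <= n_features:
            raise ValueError("max_features must lie in [1, n_features]")
        return m


@dataclass
class _Tree:
    """Post-fit tree structure in plain arrays.

    ``children_left/right``, ``feature`` and ``threshold`` describe the
    binary tree (children == -1 marks a leaf; queries with feature value
    <= threshold go left).  Leaves are described through flat CSR-style
    arrays: for leaf node v, ``leaf_slot[v]`` indexes into ``leaf_start`` /
    ``leaf_value`` / ``leaf_mode``, and the member ids/weights of slot j are
    ``member_ids[leaf_start[j]:leaf_start[j+1]]`` with aggregated normalized
    weights ``member_w[...]`` (bootstrap duplicates already merged onto the
    original sample id, each slot's weights summing to 1).
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_slot: np.ndarray       # node id -> slot (or -1 for internal nodes)
    leaf_start: np.ndarray      # slot -> offset into member arrays
    member_ids: np.ndarray      # original training-sample indices
    member_w: np.ndarray        # aggregated normalized leaf weights
    leaf_value: np.ndarray      # slot -> weighted mean response (tree prediction)
    leaf_mode: np.ndarray       # slot -> modal class code of the leaf

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Vectorized root-to-leaf routing; returns leaf slots per row."""
        node = np.zeros(len(X), dtype=np.int64)
        active = self.children_left[node] != -1
        while np.any(active):
            idx = np.nonzero(active)[0]
            cur = node[idx]
            go_left = X[idx, self.feature[cur]] <= self.threshold[cur]
            node[idx] = np.where(go_left, self.children_left[cur], self.children_right[cur])
            active[idx] = self.children_left[node[idx]] != -1
        return self.leaf_slot[node]


@dataclass
class ForestPrediction:
    """Per-query forest output: class votes, point class/value, tree weights."""

    class_labels: tuple
    class_votes: np.ndarray     # fraction of trees voting for each label
    point_class: int
    point_value: float
    tree_weights: np.ndarray    # w_b(x), summing to 1

    def vote(self, label) -> float:
        return float(self.class_votes[self.class_labels.index(label)])


@dataclass
class ConditionalCDF:
    """Estimated conditional distribution function on the training support."""

    support: np.ndarray   # sorted distinct training responses
    cdf: np.ndarray       # nondecreasing step values, last == 1

    def quantile(self, level: float) -> float:
        if not 0.0 < level <= 1.0:
            raise ValueError("quantile level must lie in (0, 1]")
        idx = int(np.argmax(self.cdf >= level - 1e-12))
        return float(self.support[idx])


class SauronForest:
    """Fitted ensemble; build with :func:`fit_forest` or :meth:`load`."""

    def __init__(self, trees: list[_Tree], y_train: np.ndarray, class_labels: tuple,
                 modal_class: int, params: ForestParams, n_features: int):
        self.trees = trees
        self.y_train = np.asarray(y_train, dtype=float)
        self.class_labels = tuple(class_labels)   # ascending class-code order
        self.modal_class = modal_class
        self.params = params
        self.n_features = n_features

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    # ---------------------------------------------------------------- fitting

    # ------------------------------------------------------------- prediction

    def _as_matrix(self, x: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = x[None, :] if single else x
        if X.shape[1] != self.n_features:
            raise ValueError("query has wrong number of features")
        return X, single

    def _apply_all(self, X: np.ndarray) -> np.ndarray:
        """Leaf slots per (tree, query): shape (B, Q)."""
        return np.stack([t.apply(X) for t in self.trees])

    def _votes_and_weights(self, slots: np.ndarray):
        """Per-query vote fractions, point class and Eq.-style tree weights."""
        B, Q = slots.shape
        labels = np.asarray(self.class_labels)  # ascending code order
        tree_votes = np.empty((B, Q), dtype=np.int64)  # label *indices*
        for b, t in enumerate(self.trees):
            tree_votes[b] = np.searchsorted(labels, t.leaf_mode[slots[b]])
        k = len(labels)
        counts = np.zeros((Q, k), dtype=np.int64)
        for j in range(k):
            counts[:, j] = np.sum(tree_votes == j, axis=0)
        votes = counts / B
        # plurality vote, ties towards the lowest class code (labels ascending)
        point_idx = np.argmax(counts, axis=1)
        point_class = labels[point_idx]
        # tree weights: 1/B if the forest predicts the modal class, else
        # equal weight on the agreeing trees only
        agree = tree_votes == point_idx[None, :]
        tw = np.where(point_class[None, :] == self.modal_class,
                      1.0 / B,
                      agree / np.maximum(agree.sum(axis=0)[None, :], 1))
        return votes, point_class, tw, tree_votes

    def predict(self, x: np.ndarray):
        """Full forest prediction for one query (or list for a batch)."""
        X, single = self._as_matrix(x)
        slots = self._apply_all(X)
        votes, point_class, tw, _ = self._votes_and_weights(slots)
        tree_values = np.stack([t.leaf_value[slots[b]] for b, t in enumerate(self.trees)])
        values = np.sum(tw * tree_values, axis=0)
        out = [ForestPrediction(self.class_labels, votes[q], int(point_class[q]),
                                float(values[q]), tw[:, q])
               for q in range(X.shape[0])]
        return out[0] if single else out

    def predict_batch(self, X: np.ndarray):
        """Vectorized batch prediction: (values, classes, votes, tree_weights)."""
        X, _ = self._as_matrix(X)
        slots = self._apply_all(X)
        votes, point_class, tw, _ = self._votes_and_weights(slots)
        tree_values = np.stack([t.leaf_value[slots[b]] for b, t in enumerate(self.trees)])
        values = np.sum(tw * tree_values, axis=0)
        return values, point_class, votes, tw

    def sample_weights(self, x: np.ndarray) -> np.ndarray:
        """Forest-wide training-sample weights w_i(x) (rows sum to 1)."""
        X, single = self._as_matrix(x)
        W = self._sample_weight_matrix(X)
        return W[0] if single else W

    def _sample_weight_matrix(self, X: np.ndarray) -> np.ndarray:
        slots = self._apply_all(X)
        _, _, tw, _ = self._votes_and_weights(slots)
        Q, N = X.shape[0], len(self.y_train)
        W = np.zeros((Q, N), dtype=float)
        for b, t in enumerate(self.trees):
            hit = np.unique(slots[b])
            for s in hit:
                qs = np.nonzero(slots[b] == s)[0]
                lo, hi = t.leaf_start[s], t.leaf_start[s + 1]
                ids = t.member_ids[lo:hi]
                W[np.ix_(qs, ids)] += tw[b, qs][:, None] * t.member_w[lo:hi][None, :]
        return W

    def conditional_cdf(self, x: np.ndarray) -> ConditionalCDF:
        """Estimate F(y | X = x) on the training support for one query."""
        w = self.sample_weights(np.asarray(x, dtype=float))
        support, inv = np.unique(self.y_train, return_inverse=True)
        mass = np.zeros(len(support))
        np.add.at(mass, inv, w)
        return ConditionalCDF(support, np.cumsum(mass))

    def predict_quantile(self, x: np.ndarray, levels) -> np.ndarray:
        """Conditional quantiles; accepts one query or a batch and one or
        several levels.  Returns shape (n_queries, n_levels), squeezed for
        single inputs."""
        levels_arr = np.atleast_1d(np.asarray(levels, dtype=float))
        if np.any(levels_arr <= 0) or np.any(levels_arr > 1):
            raise ValueError("quantile levels must lie in (0, 1]")
        X, single = self._as_matrix(x)
        W = self._sample_weight_matrix(X)
        order = np.argsort(self.y_train, kind="stable")
        y_sorted = self.y_train[order]
        cdf = np.cumsum(W[:, order], axis=1)
        out = np.empty((X.shape[0], len(levels_arr)))
        for j, lv in enumerate(levels_arr):
            idx = np.argmax(cdf >= lv - 1e-12, axis=1)
            out[:, j] = y_sorted[idx]
        if single:
            out = out[0]
        if np.ndim(levels) == 0:
            out = out[..., 0] if not single else float(out[0])
        return out

    # ---------------------------------------------------------- serialization

    def save(self, path) -> None:
        """Serialize to a structured text (JSON) file, bit-exactly reloadable."""
        doc = {
            "format": "sauroncp-forest",
            "version": 1,
            "params": {"n_trees": self.params.n_trees,
                       "max_features": self.params.max_features,
                       "min_leaf": self.params.min_leaf,
                       "seed": self.params.seed},
            "n_features": self.n_features,
            "class_labels": list(self.class_labels),
            "modal_class": self.modal_class,
            "y_train": self.y_train.tolist(),
            "trees": [
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "leaf_slot": t.leaf_slot.tolist(),
                    "leaf_start": t.leaf_start.tolist(),
                    "member_ids": t.member_ids.tolist(),
                    "member_w": t.member_w.tolist(),
                    "leaf_value": t.leaf_value.tolist(),
                    "leaf_mode": t.leaf_mode.tolist(),
                }
                for t in self.trees
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "SauronForest":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "sauroncp-forest":
            raise ValueError("not a sauroncp forest file")
        trees = [
            _Tree(
                np.asarray(d["children_left"], dtype=np.int64),
                np.asarray(d["children_right"], dtype=np.int64),
                np.asarray(d["feature"], dtype=np.int64),
                np.asarray(d["threshold"], dtype=float),
                np.asarray(d["leaf_slot"], dtype=np.int64),
                np.asarray(d["leaf_start"], dtype=np.int64),
                np.asarray(d["member_ids"], dtype=np.int64),
                np.asarray(d["member_w"], dtype=float),
                np.asarray(d["leaf_value"], dtype=float),
                np.asarray(d["leaf_mode"], dtype=np.int64),
            )
            for d in doc["trees"]
        ]
        params = ForestParams(**doc["params"])
        return cls(trees, np.asarray(doc["y_train"], dtype=float),
                   tuple(doc["class_labels"]), doc["modal_class"], params,
                   doc["n_features"])


# ------------------------------------------------------------------- fitting


def fit_forest(X: FeatureMatrix | np.ndarray, bundle: ResponseBundle,
               weights: SampleWeights, params: ForestParams | None = None,
               store_bootstraps: bool = False) -> SauronForest:
    """Grow a SAURON forest.

    Each tree is fit on a bootstrap of size N with the w* sample weights
    entering the per-node weighted-MSE split criterion.  Leaves store their
    bootstrap members (aggregated onto original sample ids), normalized
    weights, the weighted mean response and the modal class label.
    """
    params = params or ForestParams()
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if Xv.ndim != 2:
        raise ValueError("X must be two-dimensional")
    n, p = Xv.shape
    if n != bundle.n_samples:
        raise ValueError("X and response bundle are not aligned on samples")
    if not np.all(np.isfinite(Xv)):
        raise ValueError("X contains non-finite values")
    if params.n_trees < 1:
        raise ValueError("need at least one tree")
    if n < params.min_leaf:
        raise ValueError("fewer samples than min_leaf")
    m = params.resolve_max_features(p)
    w_star = np.asarray(weights.w_star, dtype=float)
    if len(w_star) != n:
        raise ValueError("weights are not aligned with the samples")
    if w_star.sum() <= 0:
        raise ValueError("sample weights sum to zero")

    scheme = bundle.scheme
    labels_sorted = scheme.labels_sorted
    code_index = {c: i for i, c in enumerate(labels_sorted)}
    d_codes = np.asarray([code_index[c] for c in bundle.d.tolist()], dtype=np.int64)

    root = np.random.SeedSequence(params.seed)
    streams = root.spawn(params.n_trees)
    trees: list[_Tree] = []
    bootstraps: list[np.ndarray] = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        boot = rng.integers(0, n, size=n)
        tree_seed = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        dt = DecisionTreeRegressor(max_features=m, min_samples_leaf=params.min_leaf,
                                   random_state=tree_seed)
        sw = w_star[boot]
        if sw.sum() <= 0:
            # degenerate bootstrap (all zero-weight samples): fall back to
            # uniform so the tree is still well-defined
            sw = np.ones(n)
        dt.fit(Xv[boot], bundle.y[boot], sample_weight=sw)
        trees.append(_build_tree(dt, Xv, bundle.y, d_codes, w_star, boot,
                                 np.asarray(labels_sorted)))
        if store_bootstraps:
            bootstraps.append(boot)
    forest = SauronForest(trees, bundle.y, labels_sorted, scheme.modal_class, params, p)
    if store_bootstraps:
        forest.bootstraps = bootstraps
        forest.w_star = w_star
    return forest


def _build_tree(dt: DecisionTreeRegressor, Xv: np.ndarray, y: np.ndarray,
                d_codes: np.ndarray, w_star: np.ndarray, boot: np.ndarray,
                labels_sorted: np.ndarray) -> _Tree:
    t = dt.tree_
    children_left = t.children_left.astype(np.int64)
    children_right = t.children_right.astype(np.int64)
    feature = t.feature.astype(np.int64)
    threshold = t.threshold.astype(float)

    leaf_nodes = np.nonzero(children_left == -1)[0]
    leaf_slot = np.full(len(children_left), -1, dtype=np.int64)
    leaf_slot[leaf_nodes] = np.arange(len(leaf_nodes))

    n_slots = len(leaf_nodes)
    # route the bootstrap rows with the package's own float64 traversal so
    # training membership and later queries follow identical comparisons
    skeleton = _Tree(children_left, children_right, feature, threshold,
                     leaf_slot, np.zeros(n_slots + 1, dtype=np.int64),
                     np.empty(0, dtype=np.int64), np.empty(0), np.empty(n_slots),
                     np.empty(n_slots, dtype=np.int64))
    boot_leaves = skeleton.apply(Xv[boot])
    leaf_start = [0]
    member_ids: list[int] = []
    member_w: list[float] = []
    leaf_value = np.empty(n_slots)
    leaf_mode = np.empty(n_slots, dtype=np.int64)
    k = len(labels_sorted)
    for s in range(n_slots):
        members = boot[boot_leaves == s]       # bootstrap multiset, original ids
        ws = w_star[members]
        total = ws.sum()
        if total <= 0:
            # all members have zero w* (possible under distance schemes);
            # fall back to equal weights within the leaf
            ws = np.ones(len(members))
            total = ws.sum()
        # aggregate duplicates onto original sample ids
        ids, inv = np.unique(members, return_inverse=True)
        agg = np.zeros(len(ids))
        np.add.at(agg, inv, ws / total)
        member_ids.extend(ids.tolist())
        member_w.extend(agg.tolist())
        leaf_start.append(len(member_ids))
        leaf_value[s] = float(np.dot(agg, y[ids]))
        # unweighted mode of the bootstrap members' classes, tie -> lowest code
        cnt = np.bincount(d_codes[members], minlength=k)
        leaf_mode[s] = labels_sorted[int(np.argmax(cnt))]
    return _Tree(children_left, children_right, feature, threshold, leaf_slot,
                 np.asarray(leaf_start, dtype=np.int64),
                 np.asarray(member_ids, dtype=np.int64),
                 np.asarray(member_w, dtype=float), leaf_value, leaf_mode)


# -------------------------------------------------- functional operation API


def tree_predict(forest: SauronForest, tree_id: int, x: np.ndarray) -> float:
    """Prediction of a single tree: the leaf's weighted mean response."""
    if not 0 <= tree_id < forest.n_trees:
        raise IndexError("tree_id out of range")
    X, _ = forest._as_matrix(x)
    t = forest.trees[tree_id]
    return float(t.leaf_value[t.apply(X)[0]])


def forest_predict(forest: SauronForest, x: np.ndarray) -> ForestPrediction:
    return forest.predict(x)


def forest_sample_weights(forest: SauronForest, x: np.ndarray) -> np.ndarray:
    return forest.sample_weights(x)


def predict_quantile(forest: SauronForest, x: np.ndarray, level: float) -> float:
    return forest.predict_quantile(x, float(level))
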