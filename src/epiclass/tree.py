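"""CART-style decision tree and random-forest attribute importance.

The classifier is a binary tree grown by recursive partitioning: at every
node the (attribute, threshold) pair maximizing the Gini impurity decrease

    dG = g(parent) - (n_L * g(L) + n_R * g(R)) / n,    g = 1 - p1^2 - p2^2

is chosen, with candidate thresholds at midpoints between consecutive
distinct sorted values.  Ties are broken deterministically: lowest attribute
index, then lowest threshold.  A node's predicted epitope probability is the
epitope fraction of its training rows, so leaf scores live on [0, 1] and a
k-mer-level cutoff turns them into labels.

`forest_importance` grows an ensemble of trees on bootstrap row samples with
a random sqrt(p)-sized attribute subset per split and reports the two
classic importance measures: *decreased Gini* (mean over trees of the total
row-weighted impurity decrease attributed to each attribute) and *decreased
accuracy* (mean out-of-bag accuracy drop after permuting the attribute's
values among the out-of-bag rows).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd


@dataclasses.dataclass
class TreeParams:
    max_depth: int = 12
    min_leaf: int = 5
    min_split: int = 10


@dataclasses.dataclass
class TreeNode:
    class_counts: tuple[int, int]  # (n_epitope, n_nonepitope)
    depth: int
    split_attribute: str | None = None
    attr_index: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def probability(self) -> float:
        n = self.class_counts[0] + self.class_counts[1]
        return self.class_counts[0] / n

    def n_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.left.n_nodes() + self.right.n_nodes()

    def max_depth(self) -> int:
        if self.is_leaf:
            return self.depth
        return max(self.left.max_depth(), self.right.max_depth())


def gini(class_counts: Sequence[float]) -> float:
    """Two-class Gini impurity, 1 - p1^2 - p2^2, in [0, 0.5]."""
    n = sum(class_counts)
    if n <= 0:
        raise ValueError("class counts must not all be zero")
    p = np.asarray(class_counts, dtype=float) / n
    return float(1.0 - np.sum(p * p))


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    min_leaf: int,
    feature_indices: np.ndarray | None = None,
) -> tuple[int, float, float] | None:
    """Best (attr_index, threshold, impurity_decrease) or None if no valid split.

    y is boolean (True = epitope).  Among equal decreases the lowest attribute
    index wins, then the lowest threshold.
    """
    n = len(y)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == n:
        return None
    parent = gini((n_pos, n - n_pos))
    feats = range(X.shape[1]) if feature_indices is None else feature_indices
    best: tuple[float, int, float] | None = None  # (-decrease, attr, threshold)
    for j in feats:
        order = np.argsort(X[:, j], kind="stable")
        v = X[order, j]
        cum_pos = np.cumsum(y[order])
        i = np.arange(1, n)  # left sizes
        valid = (v[:-1] < v[1:]) & (i >= min_leaf) & (n - i >= min_leaf)
        if not valid.any():
            continue
        nL = i[valid].astype(float)
        nR = n - nL
        posL = cum_pos[:-1][valid].astype(float)
        posR = n_pos - posL
        gL = 1.0 - (posL / nL) ** 2 - ((nL - posL) / nL) ** 2
        gR = 1.0 - (posR / nR) ** 2 - ((nR - posR) / nR) ** 2
        decrease = parent - (nL * gL + nR * gR) / n
        lo_v, hi_v = v[:-1][valid], v[1:][valid]
        thresholds = 0.5 * (lo_v + hi_v)
        # midpoint can round up to the right value for adjacent floats; fall
        # back to the left value so the partition matches the counted one
        thresholds = np.where(thresholds < hi_v, thresholds, lo_v)
        # lexicographic: max decrease, then min threshold within the attribute
        k = np.lexsort((thresholds, -decrease))[0]
        cand = (-decrease[k], int(j), float(thresholds[k]))
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    # impurity decrease is >= 0 for every split (concavity); zero-gain splits
    # are accepted so patterns like XOR resolve at the next level
    return best[1], best[2], -best[0]


def train_tree(
    X: np.ndarray,
    y: np.ndarray,
    attribute_names: Sequence[str],
    params: TreeParams | None = None,
    max_features: int | None = None,
    rng: np.random.Generator | None = None,
) -> TreeNode:
    """Grow a tree on matrix X (n, p) and boolean labels y (True = epitope)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, p) with one label per row")
    if len(y) < 2:
        raise ValueError("need at least 2 rows to train")
    params = params or TreeParams()
    if y.all() or not y.any():
        warnings.warn("single-class training set; returning a single leaf")
    if max_features is not None and rng is None:
        rng = np.random.default_rng(0)

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        yi = y[idx]
        node = TreeNode(class_counts=(int(yi.sum()), int(len(yi) - yi.sum())), depth=depth)
        if (
            depth >= params.max_depth
            or len(idx) < params.min_split
            or yi.all()
            or not yi.any()
        ):
            return node
        feats = None
        if max_features is not None:
            p = X.shape[1]
            feats = np.sort(rng.choice(p, size=min(max_features, p), replace=False))
        found = best_split(X[idx], yi, params.min_leaf, feats)
        if found is None:
            return node
        j, thr, _ = found
        mask = X[idx, j] <= thr
        node.attr_index = j
        node.split_attribute = attribute_names[j]
        node.threshold = thr
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    return grow(np.arange(len(y)), 0)


def predict_proba(node: TreeNode, X: np.ndarray) -> np.ndarray:
    """Epitope probability (leaf epitope fraction) for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty(len(X))

    def route(n: TreeNode, idx: np.ndarray) -> None:
        if n.is_leaf:
            out[idx] = n.probability
            return
        mask = X[idx, n.attr_index] <= n.threshold
        route(n.left, idx[mask])
        route(n.right, idx[~mask])

    route(node, np.arange(len(X)))
    return out


def predict(node: TreeNode, X: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    return predict_proba(node, X) >= cutoff


# ---------------------------------------------------------------------------
# Serialization: nested dict -> JSON text; floats survive bit-exactly because
# json round-trips Python float repr.


def tree_to_dict(node: TreeNode) -> dict[str, Any]:
    d: dict[str, Any] = {
        "class_counts": list(node.class_counts),
        "depth": node.depth,
    }
    if not node.is_leaf:
        d.update(
            split_attribute=node.split_attribute,
            attr_index=node.attr_index,
            threshold=node.threshold,
            left=tree_to_dict(node.left),
            right=tree_to_dict(node.right),
        )
    return d


def tree_from_dict(d: dict[str, Any]) -> TreeNode:
    node = TreeNode(class_counts=tuple(d["class_counts"]), depth=d["depth"])
    if "left" in d:
        node.split_attribute = d["split_attribute"]
        node.attr_index = d["attr_index"]
        node.threshold = d["threshold"]
        node.left = tree_from_dict(d["left"])
        node.right = tree_from_dict(d["right"])
    return node


def save_tree(path: str | Path, node: TreeNode, metadata: dict[str, Any] | None = None) -> None:
    payload = {"model": "epiclass-tree", "metadata": metadata or {}, "tree": tree_to_dict(node)}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_tree(path: str | Path) -> tuple[TreeNode, dict[str, Any]]:
    payload = json.loads(Path(path).read_text())
    if payload.get("model") != "epiclass-tree":
        raise ValueError(f"{path} is not an epiclass tree file")
    return tree_from_dict(payload["tree"]), payload["metadata"]


# ---------------------------------------------------------------------------
# Random-forest attribute importance


def _accumulate_gini_decrease(node: TreeNode, total: np.ndarray) -> None:
    if node.is_leaf:
        return
    n = sum(node.class_counts)
    nl, nr = sum(node.left.class_counts), sum(node.right.class_counts)
    dec = gini(node.class_counts) - (
        nl * gini(node.left.class_counts) + nr * gini(node.right.class_counts)
    ) / n
    total[node.attr_index] += n * dec
    _accumulate_gini_decrease(node.left, total)
    _accumulate_gini_decrease(node.right, total)


def forest_importance(
    X: np.ndarray,
    y: np.ndarray,
    attribute_names: Sequence[str],
    n_trees: int = 10_000,
    seed: int = 0,
    params: TreeParams | None = None,
) -> pd.DataFrame:
    """Bootstrap-ensemble importances: decreased Gini and decreased accuracy."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    mtry = max(1, int(math.sqrt(p)))
    gini_total = np.zeros(p)
    acc_drop = np.zeros(p)
    acc_counts = np.zeros(p)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        t = train_tree(X[boot], y[boot], attribute_names, params, max_features=mtry, rng=rng)
        _accumulate_gini_decrease(t, gini_total)
        if len(oob) == 0:
            continue
        base_acc = np.mean(predict(t, X[oob]) == y[oob])
        for j in range(p):
            perm = rng.permutation(len(oob))
            Xp = X[oob].copy()
            Xp[:, j] = Xp[perm, j]
            acc_drop[j] += base_acc - np.mean(predict(t, Xp) == y[oob])
            acc_counts[j] += 1
    with np.errstate(invalid="ignore"):
        mean_drop = np.where(acc_counts > 0, acc_drop / np.maximum(acc_counts, 1), 0.0)
    return pd.DataFrame(
        {
            "attribute": list(attribute_names),
            "decreased_gini": gini_total / n_trees,
            "decreased_accuracy": mean_drop,
        }
    ).set_index("attribute")
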