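"""Exact path-dependent Shapley attributions for decision-tree ensembles.

Implements the polynomial-time tree-Shapley algorithm (Lundberg et al.'s
path-dependent formulation): for every root-to-leaf path the proportion of
feature-subset extensions flowing down each branch is tracked with the
node-coverage weights, giving each feature's exact Shapley value under the
tree's own conditional expectations. Attributions satisfy local accuracy
exactly: base value plus the row sum equals the model prediction.

Works on scikit-learn ``DecisionTreeRegressor`` and
``RandomForestRegressor`` (forest attributions are the mean over trees,
matching the forest's mean prediction).
"""

from __future__ import annotations

import numpy as np


def _as_predict_dtype(X: np.ndarray) -> np.ndarray:
    """Round values through float32, as sklearn's predict does before
    comparing with split thresholds; keeps attribution traversals on
    exactly the branches the model itself takes at knife-edge values."""
    return np.asarray(X, dtype=np.float32).astype(np.float64)


class _Path:
    """Feature path with subset-proportion bookkeeping (struct-of-lists)."""

    __slots__ = ("d", "z", "o", "w")

    def __init__(self):
        self.d: list[int] = []  # feature index per path element
        self.z: list[float] = []  # fraction of zero (absent) paths
        self.o: list[float] = []  # fraction of one (present) paths
        self.w: list[float] = []  # permutation weight

    def copy(self) -> "_Path":
        p = _Path.__new__(_Path)
        p.d = self.d.copy()
        p.z = self.z.copy()
        p.o = self.o.copy()
        p.w = self.w.copy()
        return p

    def __len__(self) -> int:
        return len(self.d)


def _extend(p: _Path, pz: float, po: float, pi: int) -> None:
    l = len(p)
    p.d.append(pi)
    p.z.append(pz)
    p.o.append(po)
    p.w.append(1.0 if l == 0 else 0.0)
    for i in range(l - 1, -1, -1):
        p.w[i + 1] += po * p.w[i] * (i + 1) / (l + 1)
        p.w[i] = pz * p.w[i] * (l - i) / (l + 1)


def _unwind(p: _Path, i: int) -> None:
    l = len(p) - 1
    one, zero = p.o[i], p.z[i]
    n = p.w[l]
    for j in range(l - 1, -1, -1):
        if one != 0:
            t = p.w[j]
            p.w[j] = n * (l + 1) / ((j + 1) * one)
            n = t - p.w[j] * zero * (l - j) / (l + 1)
        else:
            p.w[j] = p.w[j] * (l + 1) / (zero * (l - j))
    for j in range(i, l):
        p.d[j] = p.d[j + 1]
        p.z[j] = p.z[j + 1]
        p.o[j] = p.o[j + 1]
    del p.d[l], p.z[l], p.o[l], p.w[l]


def _unwound_sum(p: _Path, i: int) -> float:
    l = len(p) - 1
    one, zero = p.o[i], p.z[i]
    n = p.w[l]
    total = 0.0
    for j in range(l - 1, -1, -1):
        if one != 0:
            t = n * (l + 1) / ((j + 1) * one)
            total += t
            n = p.w[j] - t * zero * (l - j) / (l + 1)
        else:
            total += p.w[j] * (l + 1) / (zero * (l - j))
    return total


def _recurse(
    node: int,
    p: _Path,
    pz: float,
    po: float,
    pi: int,
    left: np.ndarray,
    right: np.ndarray,
    feature: np.ndarray,
    threshold: np.ndarray,
    value: np.ndarray,
    weight: np.ndarray,
    x: np.ndarray,
    phi: np.ndarray,
) -> None:
    p = p.copy()
    _extend(p, pz, po, pi)
    if left[node] < 0:  # leaf
        for i in range(1, len(p)):
            w = _unwound_sum(p, i)
            phi[p.d[i]] += w * (p.o[i] - p.z[i]) * value[node]
        return
    f = feature[node]
    hot, cold = (
        (left[node], right[node])
        if x[f] <= threshold[node]
        else (right[node], left[node])
    )
    hot_z = weight[hot] / weight[node]
    cold_z = weight[cold] / weight[node]
    iz = io = 1.0
    try:
        k = p.d.index(f, 1)
    except ValueError:
        k = -1
    if k >= 0:
        iz, io = p.z[k], p.o[k]
        _unwind(p, k)
    _recurse(hot, p, hot_z * iz, io, f, left, right, feature, threshold, value, weight, x, phi)
    _recurse(cold, p, cold_z * iz, 0.0, f, left, right, feature, threshold, value, weight, x, phi)


def tree_shap_values(tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley values for one fitted sklearn regression tree.

    Returns (phi of shape (n, n_features), expected value). The expected
    value is the coverage-weighted mean over leaves, i.e. the root node's
    stored mean. Dispatches to the compiled kernel; the pure-python
    recursion below implements identical arithmetic and remains as the
    reference implementation.
    """
    from ._treeshap_kernel import shap_tree_all_samples

    t = tree.tree_
    X = np.ascontiguousarray(_as_predict_dtype(X))
    phi = np.zeros((X.shape[0], X.shape[1]))
    shap_tree_all_samples(
        np.ascontiguousarray(t.children_left.astype(np.int64)),
        np.ascontiguousarray(t.children_right.astype(np.int64)),
        np.ascontiguousarray(t.feature.astype(np.int64)),
        np.ascontiguousarray(t.threshold.astype(np.float64)),
        np.ascontiguousarray(t.value[:, 0, 0].astype(np.float64)),
        np.ascontiguousarray(t.weighted_n_node_samples.astype(np.float64)),
        X,
        phi,
        int(t.max_depth),
    )
    return phi, float(t.value[0, 0, 0])


def tree_shap_values_reference(tree, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Pure-python recursive implementation (slow; used as a cross-check)."""
    t = tree.tree_
    left = t.children_left
    right = t.children_right
    feature = t.feature
    threshold = t.threshold
    value = t.value[:, 0, 0]
    weight = t.weighted_n_node_samples
    X = _as_predict_dtype(X)
    phi = np.zeros((X.shape[0], X.shape[1]))
    for r in range(X.shape[0]):
        _recurse(
            0, _Path(), 1.0, 1.0, -1,
            left, right, feature, threshold, value, weight, X[r], phi[r],
        )
    return phi, float(value[0])


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley values for a forest: mean over trees of per-tree values."""
    X = np.asarray(X, dtype=float)
    phi = np.zeros((X.shape[0], X.shape[1]))
    base = 0.0
    trees = getattr(forest, "estimators_", None)
    if trees is None:
        trees = [forest]
    for est in trees:
        p, b = tree_shap_values(est, X)
        phi += p
        base += b
    return phi / len(trees), base / len(trees)


def conditional_expectation(tree, x: np.ndarray, known: np.ndarray) -> float:
    """Path-dependent conditional expectation E[f(x) | features in
    ``known``] for one tree: unknown splits average the children by
    coverage. Used by the permutation fallback and by test oracles."""
    t = tree.tree_
    x = _as_predict_dtype(x)

    def go(node: int) -> float:
        if t.children_left[node] < 0:
            return float(t.value[node, 0, 0])
        f = t.feature[node]
        if known[f]:
            nxt = (
                t.children_left[node]
                if x[f] <= t.threshold[node]
                else t.children_right[node]
            )
            return go(nxt)
        wl = t.weighted_n_node_samples[t.children_left[node]]
        wr = t.weighted_n_node_samples[t.children_right[node]]
        return (wl * go(t.children_left[node]) + wr * go(t.children_right[node])) / (
            wl + wr
        )

    return go(0)


def permutation_shap_values(
    forest, X: np.ndarray, n_permutations: int = 32, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Sampling-based Shapley attributions (model-agnostic fallback).

    Averages marginal contributions over seeded random feature orderings,
    using the trees' path-dependent conditional expectations. Converges to
    the exact values as ``n_permutations`` grows but satisfies local
    accuracy only approximately at finite sample size.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    rng = np.random.default_rng(seed)
    trees = getattr(forest, "estimators_", [forest])
    phi = np.zeros((n, m))
    base = float(np.mean([t.tree_.value[0, 0, 0] for t in trees]))

    def fval(x, known):
        return float(np.mean([conditional_expectation(t, x, known) for t in trees]))

    for r in range(n):
        for _ in range(n_permutations):
            order = rng.permutation(m)
            known = np.zeros(m, dtype=bool)
            prev = fval(X[r], known)
            for f in order:
                known[f] = True
                cur = fval(X[r], known)
                phi[r, f] += cur - prev
                prev = cur
    return phi / n_permutations, base
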