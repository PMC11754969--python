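"""Exact path-dependent Shapley attributions for decision-tree ensembles.

Implements the polynomial-time TreeSHAP recursion: for each sample the
algorithm walks every root-to-leaf path while maintaining, for each subset
size, the weighted proportion of feature subsets that would route the
sample to that leaf ("path-dependent" conditioning — absent features are
marginalised using the training-sample weights stored in the tree nodes).
The result is the exact Shapley value of each feature for the conditional
expectation function defined by the tree, and satisfies local accuracy:

    base_value + sum_j phi_j  ==  model output for the sample.

The core recursion is written in plain numpy scalar code and is JIT-compiled
with numba when available (pure-Python execution is used otherwise; results
are identical).
"""

from __future__ import annotations

import numpy as np

__all__ = ["tree_shap_values", "forest_shap_values"]


def _extend(pf, pz, po, pw, depth, parent_zero, parent_one, parent_feat):
    pf[depth] = parent_feat
    pz[depth] = parent_zero
    po[depth] = parent_one
    pw[depth] = 1.0 if depth == 0 else 0.0
    for i in range(depth - 1, -1, -1):
        pw[i + 1] += parent_one * pw[i] * (i + 1) / (depth + 1)
        pw[i] = parent_zero * pw[i] * (depth - i) / (depth + 1)


def _unwind(pf, pz, po, pw, depth, index):
    one = po[index]
    zero = pz[index]
    next_one = pw[depth]
    for i in range(depth - 1, -1, -1):
        if one != 0.0:
            tmp = pw[i]
            pw[i] = next_one * (depth + 1) / ((i + 1) * one)
            next_one = tmp - pw[i] * zero * (depth - i) / (depth + 1)
        else:
            pw[i] = pw[i] * (depth + 1) / (zero * (depth - i))
    # shift element metadata down; the recomputed subset weights are
    # positional and stay where the loop above left them
    for i in range(index, depth):
        pf[i] = pf[i + 1]
        pz[i] = pz[i + 1]
        po[i] = po[i + 1]


def _unwound_sum(pz, po, pw, depth, index):
    one = po[index]
    zero = pz[index]
    next_one = pw[depth]
    total = 0.0
    if one != 0.0:
        for i in range(depth - 1, -1, -1):
            tmp = next_one / ((i + 1) * one)
            total += tmp
            next_one = pw[i] - tmp * zero * (depth - i)
    else:
        for i in range(depth - 1, -1, -1):
            total += pw[i] / (zero * (depth - i))
    return total * (depth + 1)


def _recurse(cl, cr, feat, thr, val, wgt, x, phi,
             node, pf, pz, po, pw, depth, parent_zero, parent_one, parent_feat):
    pf = pf.copy()
    pz = pz.copy()
    po = po.copy()
    pw = pw.copy()
    _extend(pf, pz, po, pw, depth, parent_zero, parent_one, parent_feat)
    if cl[node] < 0:  # leaf
        leaf_value = val[node]
        for i in range(1, depth + 1):
            w = _unwound_sum(pz, po, pw, depth, i)
            phi[pf[i]] += w * (po[i] - pz[i]) * leaf_value
    else:
        f = feat[node]
        if x[f] <= thr[node]:
            hot, cold = cl[node], cr[node]
        else:
            hot, cold = cr[node], cl[node]
        hot_zero = wgt[hot] / wgt[node]
        cold_zero = wgt[cold] / wgt[node]
        iz = 1.0
        io = 1.0
        k = -1
        for i in range(1, depth + 1):
            if pf[i] == f:
                k = i
                break
        if k >= 0:
            iz = pz[k]
            io = po[k]
            _unwind(pf, pz, po, pw, depth, k)
            depth -= 1
        _recurse(cl, cr, feat, thr, val, wgt, x, phi,
                 hot, pf, pz, po, pw, depth + 1, hot_zero * iz, io, f)
        _recurse(cl, cr, feat, thr, val, wgt, x, phi,
                 cold, pf, pz, po, pw, depth + 1, cold_zero * iz, 0.0, f)


try:  # optional JIT; identical numerics either way
    from numba import njit

    _extend = njit(cache=False)(_extend)
    _unwind = njit(cache=False)(_unwind)
    _unwound_sum = njit(cache=False)(_unwound_sum)
    _recurse = njit(cache=False)(_recurse)
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba always present in CI image
    _HAVE_NUMBA = False


def _max_path_depth(cl, cr) -> int:
    # iterative depth computation
    depth = np.zeros(cl.size, dtype=np.int64)
    out = 0
    stack = [0]
    while stack:
        n = stack.pop()
        out = max(out, depth[n])
        if cl[n] >= 0:
            depth[cl[n]] = depth[n] + 1
            depth[cr[n]] = depth[n] + 1
            stack.append(cl[n])
            stack.append(cr[n])
    return int(out)


def tree_shap_values(tree_arrays, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley attributions for one tree.

    ``tree_arrays`` is a tuple ``(children_left, children_right, feature,
    threshold, values, node_weights)`` (sklearn ``tree_`` layout; leaf nodes
    have children -1).  Returns ``(phi, base)`` where ``phi`` has shape
    ``(n_samples, n_features)`` and ``base`` is the tree's root expectation.
    """
    cl, cr, feat, thr, val, wgt = (np.ascontiguousarray(a) for a in tree_arrays)
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, p = X.shape
    phi = np.zeros((n, p))
    maxd = _max_path_depth(cl, cr) + 2
    pf = np.zeros(maxd, dtype=np.int64)
    pz = np.zeros(maxd)
    po = np.zeros(maxd)
    pw = np.zeros(maxd)
    for i in range(n):
        _recurse(cl, cr, feat, thr, val, wgt, X[i], phi[i],
                 0, pf, pz, po, pw, 0, 1.0, 1.0, -1)
    return phi, float(val[0])


def _sklearn_tree_arrays(decision_tree):
    t = decision_tree.tree_
    values = t.value[:, 0, :]
    if values.shape[1] == 2:  # classifier: positive-class probability
        with np.errstate(invalid="ignore"):
            v = values[:, 1] / values.sum(axis=1)
    else:
        v = values[:, 0]
    return (
        t.children_left.astype(np.int64),
        t.children_right.astype(np.int64),
        t.feature.astype(np.int64),
        t.threshold.astype(np.float64),
        np.asarray(v, dtype=np.float64),
        t.weighted_n_node_samples.astype(np.float64),
    )


def forest_shap_values(forest, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Shapley attributions of a fitted sklearn tree ensemble.

    Attributions of the ensemble's positive-class probability, averaged over
    trees exactly as the forest averages its trees.  Returns ``(phi, base)``
    with ``base`` the expected value; ``base + phi.sum(axis=1)`` equals
    ``predict_proba[:, 1]`` for every row.
    """
    if not hasattr(forest, "estimators_"):
        raise TypeError(
            f"unsupported model {type(forest).__name__}: tree Shapley "
            "attribution requires a fitted tree ensemble"
        )
    X = np.asarray(X, dtype=np.float64)
    phi = np.zeros_like(X, dtype=np.float64)
    base = 0.0
    for est in forest.estimators_:
        p, b = tree_shap_values(_sklearn_tree_arrays(est), X)
        phi += p
        base += b
    k = len(forest.estimators_)
    return phi / k, base / k
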