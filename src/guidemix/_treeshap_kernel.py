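"""Compiled kernel for path-dependent tree-Shapley values.

The recursion is expressed iteratively over an explicit stack with
preallocated path buffers and compiled with numba when available; the
pure-numpy/python fallback implements the identical arithmetic. Both are
exercised by the test suite via the brute-force subset-enumeration oracle.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _shap_one_sample(
    left, right, feature, threshold, value, weight, x, phi, max_depth
):  # pragma: no cover - compiled
    # Path buffers: one slab per recursion depth. Element 0 of each path is
    # the dummy root entry (feature -1).
    cap = max_depth + 2
    pd = np.empty((cap, cap), dtype=np.int64)
    pz = np.empty((cap, cap), dtype=np.float64)
    po = np.empty((cap, cap), dtype=np.float64)
    pw = np.empty((cap, cap), dtype=np.float64)
    plen = np.zeros(cap, dtype=np.int64)

    # explicit stack: node, depth slab, incoming zero/one fractions, feature
    stack_node = np.empty(cap * 2, dtype=np.int64)
    stack_depth = np.empty(cap * 2, dtype=np.int64)
    stack_pz = np.empty(cap * 2, dtype=np.float64)
    stack_po = np.empty(cap * 2, dtype=np.float64)
    stack_pi = np.empty(cap * 2, dtype=np.int64)
    top = 0
    stack_node[0] = 0
    stack_depth[0] = 0
    stack_pz[0] = 1.0
    stack_po[0] = 1.0
    stack_pi[0] = -1
    top = 1

    while top > 0:
        top -= 1
        node = stack_node[top]
        depth = stack_depth[top]
        in_pz = stack_pz[top]
        in_po = stack_po[top]
        in_pi = stack_pi[top]

        # copy parent path into this slab
        if depth == 0:
            plen[0] = 0
        else:
            l_par = plen[depth - 1]
            for i in range(l_par):
                pd[depth, i] = pd[depth - 1, i]
                pz[depth, i] = pz[depth - 1, i]
                po[depth, i] = po[depth - 1, i]
                pw[depth, i] = pw[depth - 1, i]
            plen[depth] = l_par

        # EXTEND
        l = plen[depth]
        pd[depth, l] = in_pi
        pz[depth, l] = in_pz
        po[depth, l] = in_po
        pw[depth, l] = 1.0 if l == 0 else 0.0
        for i in range(l - 1, -1, -1):
            pw[depth, i + 1] += in_po * pw[depth, i] * (i + 1) / (l + 1)
            pw[depth, i] = in_pz * pw[depth, i] * (l - i) / (l + 1)
        plen[depth] = l + 1

        if left[node] < 0:
            # leaf: accumulate unwound weights
            ln = plen[depth] - 1
            for i in range(1, plen[depth]):
                one = po[depth, i]
                zero = pz[depth, i]
                nxt = pw[depth, ln]
                total = 0.0
                for j in range(ln - 1, -1, -1):
                    if one != 0.0:
                        t = nxt * (ln + 1) / ((j + 1) * one)
                        total += t
                        nxt = pw[depth, j] - t * zero * (ln - j) / (ln + 1)
                    else:
                        total += pw[depth, j] * (ln + 1) / (zero * (ln - j))
                phi[pd[depth, i]] += total * (one - zero) * value[node]
            continue

        f = feature[node]
        if x[f] <= threshold[node]:
            hot = left[node]
            cold = right[node]
        else:
            hot = right[node]
            cold = left[node]
        hot_z = weight[hot] / weight[node]
        cold_z = weight[cold] / weight[node]

        iz = 1.0
        io = 1.0
        k = -1
        for i in range(1, plen[depth]):
            if pd[depth, i] == f:
                k = i
                break
        if k >= 0:
            iz = pz[depth, k]
            io = po[depth, k]
            # UNWIND at k
            ln = plen[depth] - 1
            nxt = pw[depth, ln]
            for j in range(ln - 1, -1, -1):
                if io != 0.0:
                    t = pw[depth, j]
                    pw[depth, j] = nxt * (ln + 1) / ((j + 1) * io)
                    nxt = t - pw[depth, j] * iz * (ln - j) / (ln + 1)
                else:
                    pw[depth, j] = pw[depth, j] * (ln + 1) / (iz * (ln - j))
            for j in range(k, ln):
                pd[depth, j] = pd[depth, j + 1]
                pz[depth, j] = pz[depth, j + 1]
                po[depth, j] = po[depth, j + 1]
            plen[depth] = ln

        stack_node[top] = hot
        stack_depth[top] = depth + 1
        stack_pz[top] = hot_z * iz
        stack_po[top] = io
        stack_pi[top] = f
        top += 1
        stack_node[top] = cold
        stack_depth[top] = depth + 1
        stack_pz[top] = cold_z * iz
        stack_po[top] = 0.0
        stack_pi[top] = f
        top += 1


@njit(cache=True)
def shap_tree_all_samples(
    left, right, feature, threshold, value, weight, X, phi, max_depth
):  # pragma: no cover - compiled
    for r in range(X.shape[0]):
        _shap_one_sample(
            left, right, feature, threshold, value, weight, X[r], phi[r], max_depth
        )
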