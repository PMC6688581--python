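"""Numba kernels for CART tree construction and traversal.

The tree is held in flat parallel arrays (feature, threshold, left, right,
value); ``feature < 0`` marks a leaf.  The split search is the exact greedy
scan over every (feature, midpoint-threshold) candidate minimizing the summed
within-child SSE, with strict ``<`` comparisons so ties resolve to the lowest
feature index and then the lowest threshold -- identical semantics to a naive
double-loop enumeration, which the test suite uses as the independent oracle.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["build_tree_arrays", "predict_tree_arrays"]


@njit(cache=True)
def _best_split_range(X, y, idx, start, end, min_leaf):
    """Best split of the samples idx[start:end]; returns (feature,
    threshold, split_sse) with feature = -1 when no valid split exists."""
    m = end - start
    p = X.shape[1]
    best_sse = np.inf
    best_f = -1
    best_t = 0.0
    xs = np.empty(m)
    ys = np.empty(m)
    for f in range(p):
        for i in range(m):
            xs[i] = X[idx[start + i], f]
        order = np.argsort(xs, kind="mergesort")
        xo = xs[order]
        for i in range(m):
            ys[i] = y[idx[start + order[i]]]
        tsum = 0.0
        tsq = 0.0
        for i in range(m):
            tsum += ys[i]
            tsq += ys[i] * ys[i]
        lsum = 0.0
        lsq = 0.0
        for k in range(1, m):
            v = ys[k - 1]
            lsum += v
            lsq += v * v
            if xo[k] <= xo[k - 1]:
                continue
            if k < min_leaf or m - k < min_leaf:
                continue
            rsum = tsum - lsum
            sse = (lsq - lsum * lsum / k) \
                + ((tsq - lsq) - rsum * rsum / (m - k))
            if sse < best_sse:
                best_sse = sse
                best_f = f
                best_t = 0.5 * (xo[k - 1] + xo[k])
    return best_f, best_t, best_sse


@njit(cache=True)
def build_tree_arrays(X, y, max_depth, min_leaf):
    """Grow a greedy least-squares tree; returns flat node arrays.

    Leaves carry the mean target of their samples.  A node becomes a leaf at
    the depth limit, below 2*min_leaf samples, on constant targets, or when
    no valid split exists.
    """
    n = X.shape[0]
    max_nodes = 2 ** (max_depth + 1) - 1
    feature = np.full(max_nodes, -1, np.int64)
    threshold = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    value = np.zeros(max_nodes)
    gain = np.zeros(max_nodes)

    idx = np.arange(n)
    buf = np.empty(n, np.int64)
    # stack rows: node id, start, end, depth
    stack = np.empty((max_nodes, 4), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    stack[0, 3] = 0
    top = 1
    n_nodes = 1
    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        depth = stack[top, 3]
        m = end - start
        s = 0.0
        for i in range(start, end):
            s += y[idx[i]]
        mean = s / m
        value[node] = mean
        if depth >= max_depth or m < 2 * min_leaf:
            continue
        const = True
        first = y[idx[start]]
        for i in range(start + 1, end):
            if y[idx[i]] != first:
                const = False
                break
        if const:
            continue
        f, t, split_sse = _best_split_range(X, y, idx, start, end, min_leaf)
        if f < 0:
            continue
        ss = 0.0
        for i in range(start, end):
            d = y[idx[i]] - mean
            ss += d * d
        g = ss - split_sse
        gain[node] = g if g > 0.0 else 0.0
        feature[node] = f
        threshold[node] = t
        # stable partition of idx[start:end] around the split
        nl = 0
        nr = 0
        for i in range(start, end):
            if X[idx[i], f] <= t:
                buf[start + nl] = idx[i]
                nl += 1
            else:
                buf[end - 1 - nr] = idx[i]
                nr += 1
        for i in range(start, end):
            idx[i] = buf[i]
        left_id = n_nodes
        right_id = n_nodes + 1
        n_nodes += 2
        left[node] = left_id
        right[node] = right_id
        stack[top, 0] = left_id
        stack[top, 1] = start
        stack[top, 2] = start + nl
        stack[top, 3] = depth + 1
        top += 1
        stack[top, 0] = right_id
        stack[top, 1] = start + nl
        stack[top, 2] = end
        stack[top, 3] = depth + 1
        top += 1
    return (feature[:n_nodes], threshold[:n_nodes], left[:n_nodes],
            right[:n_nodes], value[:n_nodes], gain[:n_nodes])


@njit(cache=True)
def predict_tree_arrays(feature, threshold, left, right, value, X):
    n = X.shape[0]
    out = np.empty(n)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]
    return out
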