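"""Numba-jitted extremely-randomized forest impurity importance.

A minimal binary-classification forest used as the fast importance backend
for Boruta runs inside resampling loops, where thousands of forest fits on
~900-column shadow-augmented matrices are needed.  Trees are grown with the
extremely-randomized scheme (random candidate features, one uniform random
threshold each, best Gini gain among candidates) on the full sample (no
bootstrap), and importance is the normalized total Gini decrease, matching
the mean-decrease-impurity importance of conventional random forests.

Deterministic given the seed.  The first call in a process pays the JIT
compilation cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _gini(n0: float, n1: float) -> float:
    n = n0 + n1
    if n == 0.0:
        return 0.0
    p0 = n0 / n
    p1 = n1 / n
    return 1.0 - p0 * p0 - p1 * p1


@njit(cache=True)
def _grow_tree(X, y, idx, mf, max_depth, min_leaf, seed, imp):
    """Grow one extra-random tree in place, accumulating impurity decrease."""
    n, p = X.shape
    np.random.seed(seed)
    stack_s = np.empty(4 * n + 8, np.int64)
    stack_e = np.empty(4 * n + 8, np.int64)
    stack_d = np.empty(4 * n + 8, np.int64)
    stack_s[0] = 0
    stack_e[0] = n
    stack_d[0] = 0
    top = 1
    total = float(n)
    while top > 0:
        top -= 1
        s = stack_s[top]
        e = stack_e[top]
        d = stack_d[top]
        m = e - s
        n1 = 0
        for i in range(s, e):
            n1 += y[idx[i]]
        n0 = m - n1
        if m < 2 * min_leaf or d >= max_depth or n1 == 0 or n0 == 0:
            continue
        node_gini = _gini(n0, n1)
        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        for _ in range(mf):
            f = np.random.randint(0, p)
            lo = X[idx[s], f]
            hi = lo
            for i in range(s + 1, e):
                v = X[idx[i], f]
                if v < lo:
                    lo = v
                elif v > hi:
                    hi = v
            if hi <= lo:
                continue
            thr = lo + (hi - lo) * np.random.random()
            l1 = 0
            lc = 0
            for i in range(s, e):
                if X[idx[i], f] <= thr:
                    lc += 1
                    l1 += y[idx[i]]
            if lc < min_leaf or (m - lc) < min_leaf:
                continue
            r1 = n1 - l1
            gain = (
                node_gini
                - (lc / m) * _gini(lc - l1, l1)
                - ((m - lc) / m) * _gini((m - lc) - r1, r1)
            )
            if gain > best_gain:
                best_gain = gain
                best_f = f
                best_thr = thr
        if best_f < 0:
            continue
        i = s
        j = e - 1
        while i <= j:
            if X[idx[i], best_f] <= best_thr:
                i += 1
            else:
                t = idx[i]
                idx[i] = idx[j]
                idx[j] = t
                j -= 1
        if i == s or i == e:  # degenerate partition guard
            continue
        imp[best_f] += (m / total) * best_gain
        stack_s[top] = s
        stack_e[top] = i
        stack_d[top] = d + 1
        top += 1
        stack_s[top] = i
        stack_e[top] = e
        stack_d[top] = d + 1
        top += 1


@njit(cache=True)
def _forest_importance(X, y, n_trees, mf, max_depth, min_leaf, seed):
    n, p = X.shape
    imp = np.zeros(p)
    idx = np.empty(n, np.int64)
    for t in range(n_trees):
        for i in range(n):
            idx[i] = i
        _grow_tree(X, y, idx, mf, max_depth, min_leaf, seed + 7919 * t + 1, imp)
    s = imp.sum()
    if s > 0.0:
        imp /= s
    return imp


def fast_forest_importance(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 80,
    max_features: int | str = "sqrt",
    max_depth: int | None = 8,
    min_samples_leaf: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Normalized Gini-decrease importances from an extra-random forest."""
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = np.ascontiguousarray(y, dtype=np.int64)
    p = X.shape[1]
    if max_features == "sqrt" or max_features is None:
        mf = max(1, int(round(np.sqrt(p))))
    else:
        mf = max(1, min(int(max_features), p))
    depth = 10_000 if max_depth is None else int(max_depth)
    return _forest_importance(
        X, y, int(n_trees), mf, depth, int(min_samples_leaf), int(seed) % 2**31
    )
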