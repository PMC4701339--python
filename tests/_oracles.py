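"""Independent brute-force oracles used to validate the production code.

Everything here is deliberately naive: explicit Python loops and literal
transliterations of the defining formulas, sharing no code with the package.
"""

from itertools import combinations
from math import sqrt

import numpy as np


def sampen_counts_naive(series, m, r):
    """O(N^2) double-loop template counts (A, B) for sample entropy.

    Ordered pairs i != j over the first N - m templates; Chebyshev distance;
    matches at length m (B) and m + 1 (A).
    """
    x = [float(v) for v in series]
    n = len(x)
    n_templates = n - m
    a = 0
    b = 0
    for i in range(n_templates):
        for j in range(n_templates):
            if i == j:
                continue
            d_m = max(abs(x[i + t] - x[j + t]) for t in range(m))
            if d_m <= r:
                b += 1
                d_m1 = max(d_m, abs(x[i + m] - x[j + m]))
                if d_m1 <= r:
                    a += 1
    return a, b


def _euclid(u, v):
    return sqrt(sum((a - b) ** 2 for a, b in zip(u, v)))


def _class_neighbors(x, X, y, label, k):
    """Members of one class sorted by distance (stable on ties), first k."""
    items = [(i, _euclid(x, X[i])) for i in range(len(X)) if y[i] == label]
    items.sort(key=lambda t: t[1])  # Python sort is stable: index breaks ties
    return items[: min(k, len(items))]


def lmknn_score_naive(x, X, y, label, k):
    """Distance from x to the arithmetic mean of the class's k nearest points."""
    neigh = _class_neighbors(x, X, y, label, k)
    dim = len(x)
    mean = [sum(X[i][d] for i, _ in neigh) / len(neigh) for d in range(dim)]
    return _euclid(x, mean)

def pnn_score_naive(x, X, y, label, k):
    """Weighted distance sum: w_j = 1/j over the class's sorted neighbours."""
    neigh = _class_neighbors(x, X, y, label, k)
    return sum((1.0 / (j + 1)) * d for j, (_, d) in enumerate(neigh))


def lmpnn_score_naive(x, X, y, label, k):
    """Weighted sum of distances to cumulative local means of the first j."""
    neigh = _class_neighbors(x, X, y, label, k)
    dim = len(x)
    total = 0.0
    running = [0.0] * dim
    for j, (i, _) in enumerate(neigh, start=1):
        for d in range(dim):
            running[d] += X[i][d]
        mean = [v / j for v in running]
        total += (1.0 / j) * _euclid(x, mean)
    return total


def ranksum_exact_enumeration(a, b):
    """Exact two-sided rank-sum p-value by enumerating rank assignments.

    Assumes tie-free pooled data. Enumerates every way the first group's
    ranks could fall among the pooled ranks; the two-sided p-value is the
    null probability of a rank sum at least as far from its mean as observed.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    n, m = len(a), len(b)
    mean_w = n * (n + m + 1) / 2.0
    extreme = 0
    total = 0
    for combo in combinations(range(1, n + m + 1), n):
        total += 1
        if abs(sum(combo) - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            extreme += 1
    return extreme / total


def spearman_rho_naive(x, y):
    """Pearson correlation of mid-rank vectors, computed directly."""

    def midranks(v):
        v = list(map(float, v))
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for t in range(i, j + 1):
                ranks[order[t]] = avg
            i = j + 1
        return ranks

    rx = np.asarray(midranks(x))
    ry = np.asarray(midranks(y))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
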