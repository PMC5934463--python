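"""Independent brute-force reference implementations used only by tests.

Each oracle evaluates its definition literally (double/triple loops,
recomputation from raw member pairs) with none of the vectorized machinery
of the package, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_cross_correlation(y_i, y_j, d: int) -> np.ndarray:
    """Literal evaluation of the truncated-sum / full-norm definition:
    r(tau) = sum_{t=0}^{N-1-tau} y_i[t] y_j[t+tau] / (||y_i|| ||y_j||),
    r(-tau) = r_ji(tau)."""
    y_i = np.asarray(y_i, float)
    y_j = np.asarray(y_j, float)
    n = len(y_i)
    denom = math.sqrt(sum(v * v for v in y_i)) * math.sqrt(sum(v * v for v in y_j))
    r = np.zeros(2 * d + 1)
    if denom == 0:
        return r
    for tau in range(d + 1):
        s_pos = sum(y_i[t] * y_j[t + tau] for t in range(n - tau))
        s_neg = sum(y_j[t] * y_i[t + tau] for t in range(n - tau))
        r[d + tau] = s_pos / denom
        r[d - tau] = s_neg / denom
    return r


def naive_peak_pick(r: np.ndarray, d: int) -> float:
    """Signed value at the lag of max |r|; ties -> smallest |tau|, then
    negative lag."""
    order = [0]
    for tau in range(1, d + 1):
        order.extend([-tau, tau])
    best_val, best_abs = None, -1.0
    for tau in order:
        val = r[d + tau]
        if abs(val) > best_abs:
            best_val, best_abs = val, abs(val)
    return best_val


def naive_weighted_clustering(A: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Triple-loop triangle-intensity clustering coefficient with
    max-weight normalization: C_i = 2 l_i / (k_i (k_i - 1)), l_i over
    unordered neighbor pairs {j, h}."""
    n = A.shape[0]
    wmax = W.max()
    C = np.zeros(n)
    if wmax == 0:
        return C
    for i in range(n):
        k = int(A[i].sum())
        if k < 2:
            continue
        l_i = 0.0
        for j in range(n):
            if not A[i, j]:
                continue
            for h in range(j + 1, n):
                if A[i, h] and A[j, h]:
                    l_i += ((W[i, j] / wmax) * (W[j, h] / wmax) * (W[h, i] / wmax)) ** (1 / 3)
        C[i] = 2.0 * l_i / (k * (k - 1))
    return C


def naive_upgma(D: np.ndarray):
    """Quadratic-time UPGMA recomputing every inter-cluster distance from
    raw member pairs at each step; ties broken toward the lowest index
    pair.  Returns a list of (members_a, members_b, height) merges."""
    n = D.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = np.mean([D[x, y] for x in clusters[a] for y in clusters[b]])
                if best is None or dist < best[0] - 1e-15:
                    best = (dist, a, b)
        dist, a, b = best
        merges.append((list(clusters[a]), list(clusters[b]), dist))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return merges


def naive_upgma_labels(merges, n: int, h: float) -> np.ndarray:
    """Flat partition from applying the oracle merges of height <= h."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, height in merges:
        if height <= h:
            parent[find(a[0])] = find(b[0])
    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for i in range(n):
        root = find(i)
        if root not in seen:
            seen[root] = len(seen)
        labels[i] = seen[root]
    return labels
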