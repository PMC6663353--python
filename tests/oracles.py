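"""Independent brute-force oracles used to validate the fast implementations.

Everything here works by exhaustive enumeration on small graphs and shares
no code with the package internals.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def brute_shortest_distance(weights: np.ndarray, i: int, j: int) -> float:
    """Shortest inverse-weight path length by enumerating all simple paths."""
    n = len(weights)
    if i == j:
        return 0.0
    best = np.inf
    others = [v for v in range(n) if v not in (i, j)]
    for r in range(len(others) + 1):
        for mid in permutations(others, r):
            path = (i, *mid, j)
            length = 0.0
            ok = True
            for a, b in zip(path[:-1], path[1:]):
                if weights[a, b] <= 0:
                    ok = False
                    break
                length += 1.0 / weights[a, b]
            if ok:
                best = min(best, length)
    return best


def brute_distance_matrix(weights: np.ndarray) -> np.ndarray:
    n = len(weights)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                d[i, j] = brute_shortest_distance(weights, i, j)
    return d


def brute_ndi(weights: np.ndarray, i_max: float = 1.0) -> np.ndarray:
    """NDI by definition: per-removal exhaustive all-pairs recomputation."""
    n = len(weights)
    d_full = brute_distance_matrix(weights)
    info_full = np.where(np.isfinite(d_full) & (d_full > 0), 1.0 / np.where(d_full > 0, d_full, 1), 0.0) / i_max
    ndi = np.zeros(n)
    for m in range(n):
        keep = [v for v in range(n) if v != m]
        sub = weights[np.ix_(keep, keep)]
        d_sub = brute_distance_matrix(sub)
        info_sub = np.where(np.isfinite(d_sub) & (d_sub > 0), 1.0 / np.where(d_sub > 0, d_sub, 1), 0.0) / i_max
        delta = np.zeros(len(keep))
        for a, i in enumerate(keep):
            losses = []
            for b, j in enumerate(keep):
                if i == j:
                    continue
                if info_full[i, j] > 0 and info_sub[a, b] == 0:
                    losses.append(1.0)
                else:
                    val = info_full[i, j] - info_sub[a, b]
                    losses.append(val if abs(val) > 1e-12 else 0.0)
            delta[a] = np.mean(losses)
        ndi[m] = delta.mean()
    return ndi


def brute_transitivity(weights: np.ndarray) -> float:
    """Weighted transitivity by explicit triangle/triple enumeration."""
    n = len(weights)
    closed = 0.0
    triples = 0
    for i in range(n):
        neigh = [j for j in range(n) if weights[i, j] > 0]
        triples += len(neigh) * (len(neigh) - 1)
        for j, h in combinations(neigh, 2):
            if weights[j, h] > 0:
                closed += 2 * (weights[i, j] * weights[i, h] * weights[j, h]) ** (1 / 3)
    return closed / triples if triples else float("nan")


def brute_efficiency(weights: np.ndarray) -> float:
    n = len(weights)
    d = brute_distance_matrix(weights)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_assortativity(weights: np.ndarray) -> float:
    """Endpoint-strength correlation over the undirected edge list."""
    n = len(weights)
    s = weights.sum(axis=1)
    xs, ys = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if weights[i, j] > 0:
                xs.append(s[i])
                ys.append(s[j])
    x = np.array(xs)
    y = np.array(ys)
    m = len(x)
    if m < 2:
        return float("nan")
    mid = ((x + y) / 2).sum() / m
    num = (x * y).sum() / m - mid**2
    den = ((x**2 + y**2) / 2).sum() / m - mid**2
    return num / den if den > 0 else float("nan")
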