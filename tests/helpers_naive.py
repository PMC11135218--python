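"""Independent brute-force oracles used by the tests.

Everything here recomputes quantities from first principles (double
loops, exhaustive enumeration, definitional formulas) so it stays
independent of the vectorized implementations it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_metric(x, y, metric: str) -> float:
    diffs = [abs(a - b) for a, b in zip(x, y)]
    if metric == "euclidean":
        return math.sqrt(sum(d * d for d in diffs))
    if metric == "manhattan":
        return sum(diffs)
    if metric == "maximum":
        return max(diffs)
    raise ValueError(metric)


def naive_pairwise(values: np.ndarray, metric: str) -> np.ndarray:
    n = values.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = naive_metric(values[i], values[j], metric)
    return out


def _cluster_dissimilarity(d: np.ndarray, a: list[int], b: list[int], method: str) -> float:
    cross = [d[i, j] for i in a for j in b]
    if method == "single":
        return min(cross)
    if method == "complete":
        return max(cross)
    if method == "average":
        return sum(cross) / len(cross)
    if method == "ward":
        # generalized Ward (variance-increase) from the original matrix:
        # 2|A||B|/(|A|+|B|) * (S_AB/(|A||B|) - T_AA/(2|A|^2) - T_BB/(2|B|^2)),
        # which the Lance-Williams ward recurrence reproduces exactly for
        # any symmetric hollow input (linearity + full-dimensionality of
        # the squared-Euclidean cone).
        na, nb = len(a), len(b)
        s_ab = sum(cross)
        t_aa = sum(d[i, j] for i in a for j in a)
        t_bb = sum(d[i, j] for i in b for j in b)
        gap = s_ab / (na * nb) - t_aa / (2 * na * na) - t_bb / (2 * nb * nb)
        return 2.0 * na * nb / (na + nb) * gap
    raise ValueError(method)


def naive_linkage(d: np.ndarray, method: str):
    """O(n^3) agglomeration recomputing every dissimilarity from scratch.

    Same tie rule as the implementation: lexicographically least
    (smaller node id, larger node id).  Returns merge tuples
    (left, right, height, size).
    """
    n = d.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            val = _cluster_dissimilarity(d, clusters[i], clusters[j], method)
            if best is None or val < best[0]:
                best = (val, i, j)
        val, i, j = best
        members = clusters.pop(i) + clusters.pop(j)
        clusters[next_id] = members
        merges.append((i, j, val, len(members)))
        next_id += 1
    return merges


def naive_silhouette(d: np.ndarray, labels: np.ndarray):
    """Per-point a, b, s by definition (loops; singleton s = 0)."""
    n = d.shape[0]
    labels = np.asarray(labels)
    ks = np.unique(labels)
    a = np.zeros(n)
    b = np.zeros(n)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a[i] = sum(d[i, j] for j in own) / len(own) if own else 0.0
        others = []
        for c in ks:
            if c == labels[i]:
                continue
            mem = [j for j in range(n) if labels[j] == c]
            others.append(sum(d[i, j] for j in mem) / len(mem))
        b[i] = min(others)
        if not own:
            s[i] = 0.0
        else:
            m = max(a[i], b[i])
            s[i] = (b[i] - a[i]) / m if m > 0 else 0.0
    return a, b, s


def naive_within(values: np.ndarray, labels: np.ndarray, metric: str) -> float:
    total = 0.0
    for c in np.unique(labels):
        mem = np.flatnonzero(labels == c)
        centroid = values[mem].mean(axis=0)
        for i in mem:
            total += naive_metric(values[i], centroid, metric)
    return total / values.shape[0]


def min_hyperedge_cut(n: int, edges: list[set[int]], k1_min: int = 1, k2_min: int = 1) -> int:
    """Exhaustive minimum cut over all bipartitions with side sizes >= k_i."""
    best = None
    items = list(range(n))
    for bits in range(1, 2 ** (n - 1)):  # item 0 always on side 0
        left = {items[i] for i in range(n) if not (bits >> i) & 1}
        right = set(items) - left
        if len(left) < k1_min or len(right) < k2_min:
            continue
        cut = sum(1 for e in edges if e & left and e & right)
        if best is None or cut < best:
            best = cut
    return best
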