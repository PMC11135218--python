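"""Agglomerative hierarchical clustering via Lance-Williams updates.

Starting from every item as a singleton, the pair of active clusters at
minimal inter-cluster dissimilarity is merged repeatedly; dissimilarities
from the merged cluster to every other active cluster are maintained by
the Lance-Williams recurrence of the chosen linkage:

* ``single``   d(i+j, k) = min(d(i,k), d(j,k))
* ``complete`` d(i+j, k) = max(d(i,k), d(j,k))
* ``average``  d(i+j, k) = (n_i d(i,k) + n_j d(j,k)) / (n_i + n_j)
* ``ward``     d(i+j, k) = ((n_i+n_k) d(i,k) + (n_j+n_k) d(j,k) - n_k d(i,j))
                           / (n_i + n_j + n_k)

Ward heights are reported on the variance-increase (Lance-Williams)
scale without square-rooting; its variance interpretation assumes
squared-Euclidean geometry, but the update is applied verbatim to
whatever dissimilarity matrix is supplied (Manhattan and maximum
included), so every cell of the metric x linkage grid is well defined.

Ties in the minimal dissimilarity are broken deterministically: the pair
whose (smaller node id, larger node id) is lexicographically least wins.
Leaves are numbered 0..n-1 and internal nodes n..2n-2 in merge order.
All four linkages are monotone, so merge heights never decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metric_space import DistanceMatrix
from .partition import ClusterAssignment

LINKAGES: tuple[str, ...] = ("single", "complete", "average", "ward")


@dataclass
class Dendrogram:
    """Ordered merge list encoding one hierarchical tree.

    Merge ``i`` creates internal node ``n_leaves + i`` from child nodes
    ``left[i]`` and ``right[i]`` (with ``left < right``) at ``height[i]``;
    ``size[i]`` counts its leaves.
    """

    n_leaves: int
    left: np.ndarray = field(repr=False)
    right: np.ndarray = field(repr=False)
    height: np.ndarray = field(repr=False)
    size: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=np.intp)
        self.right = np.asarray(self.right, dtype=np.intp)
        self.height = np.asarray(self.height, dtype=float)
        self.size = np.asarray(self.size, dtype=np.intp)
        m = self.n_leaves - 1
        for arr in (self.left, self.right, self.height, self.size):
            if arr.shape != (m,):
                raise ValueError(f"expected {m} merges")

    @property
    def n_merges(self) -> int:
        return self.n_leaves - 1

    def merges(self) -> list[tuple[int, int, float, int]]:
        return [
            (int(l), int(r), float(h), int(s))
            for l, r, h, s in zip(self.left, self.right, self.height, self.size)
        ]

    def leaf_members(self) -> list[np.ndarray]:
        """Leaf index set of every node, leaves first then merge order."""
        members: list[np.ndarray] = [np.array([i]) for i in range(self.n_leaves)]
        for l, r in zip(self.left, self.right):
            members.append(np.concatenate([members[l], members[r]]))
        return members


def linkage_tree(D: DistanceMatrix, method: str) -> Dendrogram:
    """Agglomerate a distance matrix under one linkage method."""
    if method not in LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; choose from {LINKAGES}")
    n = D.n
    if n < 1:
        raise ValueError("need at least one item")
    if n == 1:
        z = np.zeros(0)
        return Dendrogram(1, z, z, z, z)

    total = 2 * n - 1
    # cur[a, b] = dissimilarity between active nodes a and b
    cur = np.full((total, total), np.inf)
    cur[:n, :n] = D.d
    np.fill_diagonal(cur, np.inf)
    active = np.zeros(total, dtype=bool)
    active[:n] = True
    sizes = np.ones(total, dtype=np.intp)

    left = np.empty(n - 1, dtype=np.intp)
    right = np.empty(n - 1, dtype=np.intp)
    height = np.empty(n - 1)
    size = np.empty(n - 1, dtype=np.intp)

    for step in range(n - 1):
        ids = np.flatnonzero(active)
        sub = cur[np.ix_(ids, ids)]
        minval = sub.min()
        # lexicographically least (smaller id, larger id) among ties:
        # row-major scan of the upper triangle of the sorted-id submatrix
        iu = np.triu_indices(len(ids), k=1)
        tie = np.flatnonzero(sub[iu] == minval)[0]
        i, j = ids[iu[0][tie]], ids[iu[1][tie]]

        node = n + step
        left[step], right[step] = i, j
        height[step] = minval
        sizes[node] = sizes[i] + sizes[j]
        size[step] = sizes[node]

        others = ids[(ids != i) & (ids != j)]
        if others.size:
            dik, djk = cur[i, others], cur[j, others]
            if method == "single":
                new = np.minimum(dik, djk)
            elif method == "complete":
                new = np.maximum(dik, djk)
            elif method == "average":
                ni, nj = sizes[i], sizes[j]
                new = (ni * dik + nj * djk) / (ni + nj)
            else:  # ward
                ni, nj = sizes[i], sizes[j]
                nk = sizes[others]
                new = ((ni + nk) * dik + (nj + nk) * djk - nk * minval) / (ni + nj + nk)
            cur[node, others] = new
            cur[others, node] = new
        active[i] = active[j] = False
        active[node] = True

    return Dendrogram(n, left, right, height, size)


def _labels_from_kept_merges(tree: Dendrogram, n_kept: int, item_ids) -> ClusterAssignment:
    n = tree.n_leaves
    parent = np.arange(n, dtype=np.intp)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    # map node id -> representative leaf
    rep = np.arange(2 * n - 1, dtype=np.intp)
    for idx in range(tree.n_merges):
        l, r = tree.left[idx], tree.right[idx]
        rl, rr = rep[l], rep[r]
        rep[n + idx] = rl
        if idx < n_kept:
            parent[find(rr)] = find(rl)
    labels = np.fromiter((find(i) for i in range(n)), dtype=np.intp, count=n)
    return ClusterAssignment.from_labels(item_ids, labels)


def cut_at_height(tree: Dendrogram, h: float, item_ids=None) -> ClusterAssignment:
    """Clusters left after removing every merge above height ``h``.

    Any real ``h`` is valid: below the first merge all items are
    singletons, at or above the root height everything is one cluster.
    Labels 0..k-1 are assigned in order of smallest member index.
    """
    if item_ids is None:
        item_ids = [str(i) for i in range(tree.n_leaves)]
    if tree.n_leaves == 1:
        return ClusterAssignment.from_labels(item_ids, [0])
    n_kept = int(np.searchsorted(tree.height, h, side="right"))
    return _labels_from_kept_merges(tree, n_kept, item_ids)


def cut_into_k(tree: Dendrogram, k: int, item_ids=None) -> ClusterAssignment:
    """Undo the last ``k - 1`` merges, yielding exactly ``k`` clusters."""
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if item_ids is None:
        item_ids = [str(i) for i in range(n)]
    return _labels_from_kept_merges(tree, n - k, item_ids)
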