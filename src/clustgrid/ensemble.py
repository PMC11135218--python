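"""Consensus clustering: CSPA, HGPA and MCLA over a set of base partitions.

All three consume base :class:`~clustgrid.partition.ClusterAssignment`
objects over the same items and a fixed target cluster count ``k``
(conventionally the cluster count chosen by the best distance-linkage
combination):

* CSPA — entrywise-average co-association matrix; 1 - co-association is
  clustered with average-linkage agglomeration and cut into ``k``.
* HGPA — each base cluster is a hyperedge over the items; a balanced
  ``k``-way partition approximately minimising the number of cut
  hyperedges is found by recursive bisection of the star-expansion
  graph (spectral ordering, exact min-cut over admissible split points).
* MCLA — base clusters become meta-objects under Jaccard dissimilarity
  of their membership indicators, grouped into ``k`` metaclusters by
  average-linkage agglomeration; items join the metacluster with the
  highest mean membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment

from .agglomerate import cut_into_k, linkage_tree
from .metric_space import DistanceMatrix
from .partition import ClusterAssignment


@dataclass
class CoassociationMatrix:
    """Fraction of base clusterings placing each item pair together."""

    item_ids: list[str]
    entries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        n = len(self.item_ids)
        if self.entries.shape != (n, n):
            raise ValueError("co-association shape mismatch")
        if not np.allclose(self.entries, self.entries.T):
            raise ValueError("co-association must be symmetric")
        if (self.entries < -1e-12).any() or (self.entries > 1 + 1e-12).any():
            raise ValueError("entries must lie in [0, 1]")
        if not np.allclose(np.diag(self.entries), 1.0):
            raise ValueError("diagonal must be 1")


def _check_bases(clusterings: list[ClusterAssignment]) -> tuple[str, ...]:
    if not clusterings:
        raise ValueError("need at least one base clustering")
    ids = clusterings[0].item_ids
    for c in clusterings[1:]:
        if c.item_ids != ids:
            raise ValueError("base clusterings must share one item set")
    return ids


def coassociation_matrix(clusterings: list[ClusterAssignment]) -> CoassociationMatrix:
    """Entrywise average of the base clusterings' binary same-cluster matrices."""
    ids = _check_bases(clusterings)
    n = len(ids)
    acc = np.zeros((n, n))
    for c in clusterings:
        oh = c.onehot()
        acc += oh @ oh.T
    acc /= len(clusterings)
    np.fill_diagonal(acc, 1.0)
    return CoassociationMatrix(list(ids), acc)


def cspa(clusterings: list[ClusterAssignment], k: int) -> ClusterAssignment:
    """Cluster-based similarity partitioning: agglomerate 1 - co-association."""
    ids = _check_bases(clusterings)
    n = len(ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}")
    co = coassociation_matrix(clusterings)
    d = 1.0 - co.entries
    np.fill_diagonal(d, 0.0)
    D = DistanceMatrix(list(ids), d, metric_tag="one_minus_coassociation")
    tree = linkage_tree(D, "average")
    return cut_into_k(tree, k, item_ids=ids)


# ---------------------------------------------------------------- HGPA


def _connected_components(n: int, edges: list[np.ndarray]) -> list[list[int]]:
    """Components of the item graph where a hyperedge connects all its members."""
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        r = find(int(e[0]))
        for v in e[1:]:
            parent[find(int(v))] = r
    comp: dict[int, list[int]] = {}
    for i in range(n):
        comp.setdefault(find(i), []).append(i)
    return sorted(comp.values(), key=lambda c: c[0])


def _spectral_order(sub_items: list[int], edges: list[np.ndarray]) -> list[int]:
    """Order items by the Fiedler vector of the star-expansion graph.

    Hyperedges become auxiliary vertices connected to their members; the
    second-smallest eigenvector of the graph Laplacian orders the items.
    Disconnected inputs are ordered component-block-wise instead (each
    component kept contiguous, recursively spectrally ordered).
    """
    m = len(sub_items)
    if m <= 2:
        return list(sub_items)
    pos = {v: i for i, v in enumerate(sub_items)}
    restricted = []
    for e in edges:
        r = [pos[v] for v in e if v in pos]
        if len(r) >= 2:
            restricted.append(np.array(r))
    if not restricted:
        return list(sub_items)
    comps = _connected_components(m, restricted)
    if len(comps) > 1:
        out: list[int] = []
        for comp in comps:
            comp_items = [sub_items[i] for i in comp]
            out.extend(_spectral_order(comp_items, edges))
        return out
    ne = len(restricted)
    total = m + ne
    w = np.zeros((total, total))
    for j, r in enumerate(restricted):
        w[r, m + j] = 1.0
        w[m + j, r] = 1.0
    lap = np.diag(w.sum(axis=1)) - w
    vals, vecs = eigh(lap, subset_by_index=[1, 1])
    fiedler = vecs[: m, 0]
    order = sorted(range(m), key=lambda i: (fiedler[i], i))
    return [sub_items[i] for i in order]


def _cut_count(left: set[int], right: set[int], edges: list[np.ndarray]) -> int:
    cut = 0
    for e in edges:
        in_l = in_r = False
        for v in e:
            if v in left:
                in_l = True
            elif v in right:
                in_r = True
            if in_l and in_r:
                cut += 1
                break
    return cut


def _component_count(side: list[int], edges: list[np.ndarray]) -> int:
    pos = {v: i for i, v in enumerate(side)}
    restricted = []
    for e in edges:
        r = [pos[v] for v in e if v in pos]
        if len(r) >= 2:
            restricted.append(np.array(r))
    return len(_connected_components(len(side), restricted))


def _hgpa_partition(items: list[int], k: int, edges: list[np.ndarray], out: np.ndarray, next_label: int) -> int:
    if k == 1:
        out[items] = next_label
        return next_label + 1
    k1 = (k + 1) // 2
    k2 = k - k1
    order = _spectral_order(items, edges)
    m = len(order)
    target = m * k1 / k
    item_set = set(items)
    scoped = []
    for e in edges:
        r = np.array([v for v in e if v in item_set])
        if len(r) >= 2:
            scoped.append(r)
    # choose the admissible split minimizing cut hyperedges; among ties
    # prefer splits leaving each side at least as many hypergraph
    # components as the clusters it still has to produce (so a zero-cut
    # k-way partition, when one exists, survives the recursion), then
    # proportional balance
    best = None
    for t in range(k1, m - k2 + 1):
        left, right = order[:t], order[t:]
        cut = _cut_count(set(left), set(right), scoped)
        stranded = max(0, k1 - _component_count(left, scoped)) + max(
            0, k2 - _component_count(right, scoped)
        )
        key = (cut, stranded, abs(t - target), t)
        if best is None or key < best[0]:
            best = (key, t)
    t = best[1]
    next_label = _hgpa_partition(order[:t], k1, edges, out, next_label)
    return _hgpa_partition(order[t:], k2, edges, out, next_label)


def hgpa(clusterings: list[ClusterAssignment], k: int) -> ClusterAssignment:
    """Hypergraph-partitioning consensus (star-expansion recursive bisection).

    An approximation of hypergraph min-cut: at each bisection the items
    are ordered spectrally and the admissible split with the fewest cut
    hyperedges (ties toward proportional balance) is taken.
    """
    ids = _check_bases(clusterings)
    n = len(ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}")
    edges = [cluster for c in clusterings for cluster in c.clusters() if len(cluster) >= 2]
    out = np.empty(n, dtype=np.intp)
    _hgpa_partition(list(range(n)), k, edges, out, 0)
    return ClusterAssignment.from_labels(ids, out)


# ---------------------------------------------------------------- MCLA


def mcla(clusterings: list[ClusterAssignment], k: int) -> ClusterAssignment:
    """Metaclustering consensus: cluster the base clusters, then vote.

    Base clusters are compared by Jaccard dissimilarity of their binary
    membership indicators and grouped into ``k`` metaclusters with
    average linkage; each item joins the metacluster with the highest
    mean membership (ties toward the lower metacluster label).  Emits a
    warning when a metacluster wins no items (the output then has fewer
    than ``k`` clusters and is relabelled compactly).
    """
    ids = _check_bases(clusterings)
    n = len(ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}")
    indicators = np.stack(
        [c.onehot()[:, j] for c in clusterings for j in range(c.k)]
    )  # (n_meta, n)
    n_meta = indicators.shape[0]
    if k > n_meta:
        raise ValueError(f"target k={k} exceeds the {n_meta} base clusters")
    inter = indicators @ indicators.T
    sizes = indicators.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    np.fill_diagonal(jac, 0.0)
    D = DistanceMatrix([f"c{i}" for i in range(n_meta)], jac, metric_tag="jaccard")
    tree = linkage_tree(D, "average")
    meta = cut_into_k(tree, k)
    onehot_meta = meta.onehot()  # (n_meta, k)
    votes = (onehot_meta.T @ indicators) / onehot_meta.sum(axis=0)[:, None]  # (k, n)
    labels = votes.argmax(axis=0)  # argmax takes the lowest label on ties
    if len(np.unique(labels)) < k:
        warnings.warn(
            f"MCLA: {k - len(np.unique(labels))} metacluster(s) won no items; "
            "output has fewer clusters than requested",
            stacklevel=2,
        )
    return ClusterAssignment.from_labels(ids, labels)


def match_labels(a: ClusterAssignment, b: ClusterAssignment) -> np.ndarray:
    """Relabel ``b`` to best match ``a`` (max-agreement bipartite matching).

    Returns ``b``'s labels mapped through the optimal assignment of the
    confusion-count matrix; useful for idempotence checks up to label
    permutation.
    """
    if a.item_ids != b.item_ids:
        raise ValueError("assignments must share one item set")
    conf = a.onehot().T @ b.onehot()  # (ka, kb) agreement counts
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.full(b.k, -1, dtype=np.intp)
    mapping[cols] = rows
    spare = max(a.k, b.k)
    for j in range(b.k):
        if mapping[j] < 0:
            mapping[j] = spare
            spare += 1
    return mapping[b.labels]
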