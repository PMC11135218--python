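"""Cluster-quality scoring and the metric x linkage combination grid.

Quality of a partition is scored by two statistics:

* ``S`` — average silhouette width (ASW).  For item ``i``, ``a(i)`` is
  its mean distance to co-members, ``b(i)`` the smallest mean distance
  to another cluster, and ``s(i) = (b - a) / max(a, b)``; items in
  singleton clusters score 0 by convention.  ASW lies in [-1, 1].
* ``W`` — mean distance of items to their cluster centroid (arithmetic
  mean of member rows), under the same metric as the distances; compact
  clusters give small W.

The combined fitness ``F = S / max(W, eps)`` (eps = 1e-12) increases
with silhouette and decreases with within-cluster scatter.  Scanning
every cut point ``k = 2 .. min(n-1, k_max)`` of a dendrogram and taking
the argmax-F record picks the best cut for one (metric, linkage) cell;
repeating over all cells and taking the global argmax ranks the
combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agglomerate import LINKAGES, Dendrogram, cut_into_k, linkage_tree
from .expression_io import ExpressionMatrix
from .metric_space import METRICS, DistanceMatrix, pairwise_distance, row_distances
from .partition import ClusterAssignment, canonical_labels

EPS_W = 1e-12
DEFAULT_K_MAX = 300


@dataclass
class SilhouetteReport:
    """Per-item silhouette terms and their average."""

    a: np.ndarray = field(repr=False)
    b: np.ndarray = field(repr=False)
    s: np.ndarray = field(repr=False)
    asw: float = 0.0


@dataclass
class FitnessRecord:
    """One evaluated cut point: (S, W, F) at cluster count ``k``."""

    metric: str
    linkage: str
    cut_height: float
    k: int
    S: float
    W: float
    F: float


@dataclass
class CombinationGrid:
    """Optimal record per (metric, linkage) cell plus the argmax cell."""

    records: list[FitnessRecord]
    best: FitnessRecord

    def cell(self, metric: str, linkage: str) -> FitnessRecord:
        for r in self.records:
            if r.metric == metric and r.linkage == linkage:
                return r
        raise KeyError((metric, linkage))


def _silhouette_terms(
    d: np.ndarray, labels: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = d.shape[0]
    onehot = np.zeros((n, k))
    onehot[np.arange(n), labels] = 1.0
    counts = onehot.sum(axis=0)
    dsum = d @ onehot  # (n, k) summed distance to each cluster
    own = counts[labels]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(own > 1, dsum[np.arange(n), labels] / np.maximum(own - 1, 1), 0.0)
        mean_to = dsum / counts  # (n, k)
    mean_to[np.arange(n), labels] = np.inf
    b = mean_to.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    s[own == 1] = 0.0  # singleton convention
    return a, b, s


def silhouette_report(D: DistanceMatrix, c: ClusterAssignment) -> SilhouetteReport:
    """Silhouette widths of a partition over a distance matrix.

    Requires ``2 <= k <= n - 1``; with k = 1 there is no "other cluster"
    and with k = n every item is a singleton.
    """
    n = D.n
    if not (2 <= c.k <= n - 1):
        raise ValueError(f"silhouette needs 2 <= k <= n-1, got k={c.k}, n={n}")
    if c.n != n:
        raise ValueError("assignment does not cover the distance matrix items")
    a, b, s = _silhouette_terms(D.d, c.labels, c.k)
    return SilhouetteReport(a=a, b=b, s=s, asw=float(s.mean()))


def within_cluster_distance(
    m: ExpressionMatrix, c: ClusterAssignment, metric: str = "euclidean"
) -> float:
    """Mean metric-distance of items to their cluster centroid.

    Centroids are arithmetic means of member rows for every metric; a
    singleton contributes 0 (it sits on its own centroid).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if c.n != m.n_genes:
        raise ValueError("assignment does not cover the matrix rows")
    onehot = c.onehot()
    counts = onehot.sum(axis=0)
    centroids = (onehot.T @ m.values) / counts[:, None]
    dists = row_distances(m.values, centroids[c.labels], metric)
    return float(dists.mean())


def fitness_score(S: float, W: float) -> float:
    """Combined fitness F = S / max(W, eps): rises with silhouette, falls with scatter."""
    if not (-1.0 - 1e-9 <= S <= 1.0 + 1e-9):
        raise ValueError("S must lie in [-1, 1]")
    if W < 0:
        raise ValueError("W must be nonnegative")
    return float(S) / max(float(W), EPS_W)


def _iter_cut_labels(tree: Dendrogram, k_max: int):
    """Yield (k, labels) for k = 2..k_max by undoing merges from the top.

    Labels are canonical (numbered by smallest member index).  O(n^2)
    overall instead of replaying the merge list once per k.
    """
    n = tree.n_leaves
    members = tree.leaf_members()
    raw = np.zeros(n, dtype=np.intp)
    for k in range(2, k_max + 1):
        split = n - k  # merge index undone when moving to k clusters
        raw[members[tree.right[split]]] = k - 1
        yield k, canonical_labels(raw)


def scan_cut_points(
    m: ExpressionMatrix,
    D: DistanceMatrix,
    tree: Dendrogram,
    metric: str = "euclidean",
    k_max: int | None = None,
    linkage_tag: str = "",
) -> tuple[list[FitnessRecord], FitnessRecord]:
    """Evaluate every cut ``k = 2 .. min(n-1, k_max)`` and return the argmax-F record.

    Ties in F are broken toward smaller k (parsimony).  Degenerate input
    (e.g. identical rows, all distances zero) yields S = 0, W = 0 and
    F = 0 without error.
    """
    n = m.n_genes
    if n < 4:
        raise ValueError("cut-point scan needs at least 4 items")
    if D.n != n or tree.n_leaves != n:
        raise ValueError("matrix, distances and tree disagree on item count")
    upper = min(n - 1, k_max if k_max is not None else DEFAULT_K_MAX)
    x = m.values
    d = D.d
    heights = tree.height
    records: list[FitnessRecord] = []
    for k, labels in _iter_cut_labels(tree, upper):
        _, _, s = _silhouette_terms(d, labels, k)
        S = float(s.mean())
        onehot = np.zeros((n, k))
        onehot[np.arange(n), labels] = 1.0
        counts = onehot.sum(axis=0)
        centroids = (onehot.T @ x) / counts[:, None]
        W = float(row_distances(x, centroids[labels], metric).mean())
        records.append(
            FitnessRecord(
                metric=metric,
                linkage=linkage_tag,
                cut_height=float(heights[n - k]),
                k=k,
                S=S,
                W=W,
                F=fitness_score(S, W),
            )
        )
    best = max(records, key=lambda r: (r.F, -r.k))
    return records, best


def evaluate_grid(
    m: ExpressionMatrix,
    metrics=METRICS,
    linkages=LINKAGES,
    k_max: int | None = None,
) -> CombinationGrid:
    """One cut-point scan per (metric, linkage) cell; global argmax F wins.

    The default 3 metrics x 4 linkages yield a 12-cell grid.  Ties in F
    across cells are broken by cell order (metrics outer, linkages inner).
    """
    metrics = list(metrics)
    linkages = list(linkages)
    if not metrics or not linkages:
        raise ValueError("metric and linkage lists must be non-empty")
    cells: list[FitnessRecord] = []
    for metric in metrics:
        D = pairwise_distance(m, metric)
        for link in linkages:
            tree = linkage_tree(D, link)
            _, opt = scan_cut_points(m, D, tree, metric=metric, k_max=k_max, linkage_tag=link)
            cells.append(opt)
    best = max(cells, key=lambda r: r.F)
    return CombinationGrid(records=cells, best=best)


def grid_best_assignment(m: ExpressionMatrix, grid: CombinationGrid) -> ClusterAssignment:
    """Re-derive the partition at the grid's best cell."""
    r = grid.best
    D = pairwise_distance(m, r.metric)
    tree = linkage_tree(D, r.linkage)
    return cut_into_k(tree, r.k, item_ids=m.gene_ids)
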