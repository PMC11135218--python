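"""Pairwise gene-gene distances and optional PCA preprocessing.

Three metrics are supported, applied between gene rows over all sample
columns:

* ``euclidean`` — sqrt of summed squared coordinate differences,
* ``manhattan`` — summed absolute coordinate differences,
* ``maximum``  — largest absolute coordinate difference (Chebyshev).

Entrywise the three obey ``maximum <= euclidean <= manhattan``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .expression_io import ExpressionMatrix

METRICS: tuple[str, ...] = ("euclidean", "manhattan", "maximum")

_SCIPY_NAME = {"euclidean": "euclidean", "manhattan": "cityblock", "maximum": "chebyshev"}


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarities with zero diagonal."""

    item_ids: list[str]
    d: np.ndarray = field(repr=False)
    metric_tag: str = "euclidean"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.item_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match item count")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any():
            raise ValueError("distances must be nonnegative")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.item_ids)


def row_distances(x: np.ndarray, y: np.ndarray, metric: str) -> np.ndarray:
    """Row-wise distance between paired rows of two equal-shape arrays."""
    diff = np.abs(np.asarray(x, float) - np.asarray(y, float))
    if metric == "euclidean":
        return np.sqrt((diff**2).sum(axis=-1))
    if metric == "manhattan":
        return diff.sum(axis=-1)
    if metric == "maximum":
        return diff.max(axis=-1)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def pairwise_distance(m: ExpressionMatrix, metric: str = "euclidean") -> DistanceMatrix:
    """All gene-gene distances under one metric.

    Parameters
    ----------
    m
        Expression matrix; genes (rows) are the clustered items.
    metric
        One of ``euclidean``, ``manhattan``, ``maximum``.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    d = squareform(pdist(m.values, metric=_SCIPY_NAME[metric]))
    return DistanceMatrix(list(m.gene_ids), d, metric_tag=metric)


def reduce_dimensions(m: ExpressionMatrix, variance_fraction: float = 0.95) -> ExpressionMatrix:
    """Project gene rows onto leading principal components.

    Columns are centered but not scaled (scaling would erase the
    column-variance heterogeneity that distinguishes the metrics).  The
    smallest number of components whose cumulative explained variance
    reaches ``variance_fraction`` is kept; components with numerically
    zero variance are always dropped.  Gene IDs are preserved; sample
    IDs are replaced by synthetic component IDs ``PC1, PC2, ...``.
    """
    if not (0.0 < variance_fraction <= 1.0):
        raise ValueError("variance_fraction must be in (0, 1]")
    if m.n_samples < 2:
        raise ValueError("PCA needs at least 2 sample columns")
    centered = m.values - m.values.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    nonzero = s > (s[0] * 1e-12 if s[0] > 0 else 0.0)
    if not nonzero.any():  # constant matrix: keep a single zero component
        scores = np.zeros((m.n_genes, 1))
        return ExpressionMatrix(list(m.gene_ids), ["PC1"], scores, name=m.name)
    s = s[nonzero]
    u = u[:, nonzero]
    var = s**2
    cum = np.cumsum(var) / var.sum()
    r = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    scores = u[:, :r] * s[:r]
    return ExpressionMatrix(
        list(m.gene_ids), [f"PC{i + 1}" for i in range(r)], scores, name=m.name
    )
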