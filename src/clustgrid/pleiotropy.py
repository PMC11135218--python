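"""Cross-disease pleiotropy via summary-statistic profiles of shared genes.

Disease datasets rarely share a sample dimension (one may record 60
time stamps, another 72), so a shared gene's rows cannot be stacked
directly.  Instead each gene is summarized per dataset by four
statistics on the expression scale — mean, median, standard deviation
and variance (sample, n-1 denominator) — giving a small diseases x 4
secondary matrix per gene.  Clustering the disease rows of that matrix
(default: the best metric-linkage combination found by the grid stage)
puts diseases with similar expression behaviour of the gene on adjacent
leaves; such per-gene disease trees are the pleiotropy readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .agglomerate import Dendrogram, linkage_tree
from .expression_io import ExpressionMatrix
from .metric_space import METRICS, DistanceMatrix, _SCIPY_NAME

SUMMARY_COLUMNS = ("mean", "median", "sd", "variance")


@dataclass
class SummaryProfile:
    """Per-gene secondary matrix: one row per dataset, columns = 4 statistics."""

    gene_id: str
    dataset_names: list[str]
    stats: np.ndarray = field(repr=False)  # (n_datasets, 4)

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if self.stats.shape != (len(self.dataset_names), 4):
            raise ValueError("stats must be (n_datasets, 4)")
        sd, var = self.stats[:, 2], self.stats[:, 3]
        if (var < -1e-12).any() or not np.allclose(var, sd**2, atol=1e-9):
            raise ValueError("variance must equal sd^2 and be nonnegative")


def _names(datasets: list[ExpressionMatrix]) -> list[str]:
    return [m.name if m.name else f"dataset_{i}" for i, m in enumerate(datasets)]


def find_common_genes(datasets: list[ExpressionMatrix]) -> list[str]:
    """Gene IDs present in every dataset, sorted lexicographically."""
    if len(datasets) < 2:
        raise ValueError("need at least two datasets to intersect")
    common = set(datasets[0].gene_ids)
    for m in datasets[1:]:
        common &= set(m.gene_ids)
    return sorted(common)


def summarize_gene(gene: str, datasets: list[ExpressionMatrix]) -> SummaryProfile:
    """Mean, median, SD and variance of one gene's row in every dataset.

    SD and variance use the sample (n-1) denominator.  Raises if the
    gene is absent from any dataset, naming the dataset.
    """
    names = _names(datasets)
    rows = []
    for m, name in zip(datasets, names):
        if gene not in m.gene_ids:
            raise KeyError(f"gene {gene!r} absent from dataset {name!r}")
        x = m.row(gene)
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        rows.append([float(np.mean(x)), float(np.median(x)), sd, sd**2])
    return SummaryProfile(gene, names, np.array(rows))


def pleiotropy_tree(
    profile: SummaryProfile,
    metric: str = "maximum",
    linkage: str = "average",
    zscore_columns: bool = False,
) -> Dendrogram:
    """Hierarchical tree over the diseases of one gene's summary profile.

    Leaves are the profile's dataset rows, in order.  Diseases whose
    summary vectors are close share similar expression behaviour of the
    gene.  With ``zscore_columns`` the four statistics are standardized
    first (variance is on a squared scale and can otherwise dominate).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    n = len(profile.dataset_names)
    if n < 2:
        raise ValueError("need at least two diseases to build a tree")
    x = profile.stats
    if zscore_columns:
        sd = x.std(axis=0, ddof=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    d = squareform(pdist(x, metric=_SCIPY_NAME[metric]))
    D = DistanceMatrix(list(profile.dataset_names), d, metric_tag=metric)
    return linkage_tree(D, linkage)
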