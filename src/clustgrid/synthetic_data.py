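"""Synthetic expression matrices with planted cluster structure.

The generator emulates microarray-style matrices at the shapes the
benchmarked cancer sets come in (medium: ~2,000-7,000 genes x 60-80
samples; large: ~12,000-15,000 x 180-250 — scaled down 10x for tests):
``k`` cluster centers sit at the vertices of a regular simplex, and
every gene is its center plus Gaussian noise.  ``separation`` is
expressed in units of the RMS distance between two same-cluster genes,
``noise_sd * sqrt(2 * n_samples)``: in ``p`` dimensions that — not the
per-coordinate SD — is the scale on which point clouds overlap, so
separation 1 means clusters about as far apart as they are wide and
separation 10 means essentially disjoint clouds under every metric.  The ``heteroscedastic`` column-variance
profile multiplies each column's noise SD by a log-uniform draw from
[0.2, 5], recreating the non-uniform per-column variance under which
the maximum (Chebyshev) metric distinguishes itself.

Multi-dataset collections plant a shared subset of gene IDs across
otherwise-disjoint datasets, with dataset-specific means for the shared
genes, so the pleiotropy stage has a known ground truth.

Nothing here models probe-level physics or gene-gene correlation; see
docs/methods.md for what that implies about the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .expression_io import ExpressionMatrix

VARIANCE_PROFILES = ("uniform", "heteroscedastic")
HETERO_LOG_RANGE = (0.2, 5.0)  # log-uniform column SD multipliers


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of one planted-cluster matrix.

    ``separation`` is the distance between cluster centers in units of
    the RMS within-cluster gene-gene distance ``noise_sd * sqrt(2 *
    n_samples)``; at 10 the clusters are essentially non-overlapping,
    near 0 the data is pure noise.
    """

    n_genes: int = 200
    n_samples: int = 60
    k: int = 4
    separation: float = 10.0
    noise_sd: float = 1.0
    column_variance_profile: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("sizes must be positive")
        if not (1 <= self.k <= self.n_genes):
            raise ValueError("need 1 <= k <= n_genes")
        if self.k > self.n_samples:
            raise ValueError("simplex center placement needs k <= n_samples")
        if self.separation < 0:
            raise ValueError("separation must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.column_variance_profile not in VARIANCE_PROFILES:
            raise ValueError(f"profile must be one of {VARIANCE_PROFILES}")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth gene -> cluster labels (every cluster non-empty)."""

    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.intp))


def _simplex_centers(k: int, n_samples: int, pairwise_distance: float) -> np.ndarray:
    # scaled standard-basis vectors: |c*e_i - c*e_j| = c*sqrt(2) for i != j
    centers = np.zeros((k, n_samples))
    if k > 1:
        c = pairwise_distance / np.sqrt(2.0)
        centers[np.arange(k), np.arange(k)] = c
    return centers


def _column_multipliers(spec: PlantedSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.column_variance_profile == "uniform":
        return np.ones(spec.n_samples)
    lo, hi = HETERO_LOG_RANGE
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_samples))


def generate_planted_matrix(spec: PlantedSpec) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Draw one matrix with planted clusters; deterministic given ``spec.seed``.

    Genes are assigned to the ``k`` clusters in near-equal contiguous
    blocks; values are center + N(0, (noise_sd * column multiplier)^2).
    """
    rng = np.random.default_rng(spec.seed)
    within_rms = spec.noise_sd * np.sqrt(2.0 * spec.n_samples)
    centers = _simplex_centers(spec.k, spec.n_samples, spec.separation * within_rms)
    labels = (np.arange(spec.n_genes) * spec.k) // spec.n_genes
    mult = _column_multipliers(spec, rng)
    noise = rng.standard_normal((spec.n_genes, spec.n_samples))
    values = centers[labels] + noise * (spec.noise_sd * mult)
    width = len(str(spec.n_genes))
    gene_ids = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{j + 1}" for j in range(spec.n_samples)]
    m = ExpressionMatrix(gene_ids, sample_ids, values, name=f"planted_k{spec.k}_seed{spec.seed}")
    return m, PlantedTruth(labels)


@dataclass
class DiseaseCollection:
    """Datasets sharing a planted subset of gene IDs, with ground truth."""

    matrices: list[ExpressionMatrix]
    shared_gene_ids: list[str]
    shared_means: np.ndarray = field(repr=False)  # (n_shared, n_datasets)


def generate_disease_collection(
    n_datasets: int,
    shared_gene_count: int,
    per_dataset_spec: list[PlantedSpec],
    seed: int | None = None,
    shared_means: np.ndarray | None = None,
) -> DiseaseCollection:
    """Generate datasets whose gene-ID sets intersect in exactly the shared genes.

    Datasets may have unequal sample counts (the collections being
    emulated mix e.g. 60- and 72-column matrices).  Each shared gene's
    row in dataset ``d`` is its dataset-specific mean plus Gaussian
    noise at that dataset's ``noise_sd``, so its summary statistics
    differ across datasets.  Means are drawn N(0, 2) from ``seed``
    (default: first spec's seed + 1) unless supplied explicitly as an
    (n_shared, n_datasets) array.
    """
    if n_datasets < 1:
        raise ValueError("need at least one dataset")
    if len(per_dataset_spec) != n_datasets:
        raise ValueError("one PlantedSpec per dataset required")
    if shared_gene_count < 0 or any(shared_gene_count > s.n_genes for s in per_dataset_spec):
        raise ValueError("shared_gene_count must be <= every dataset's n_genes")
    if seed is None:
        seed = per_dataset_spec[0].seed + 1
    rng = np.random.default_rng(seed)
    if shared_means is None:
        shared_means = rng.normal(0.0, 2.0, size=(shared_gene_count, n_datasets))
    else:
        shared_means = np.asarray(shared_means, dtype=float)
        if shared_means.shape != (shared_gene_count, n_datasets):
            raise ValueError("shared_means must be (shared_gene_count, n_datasets)")
    shared_ids = [f"SHARED-{g + 1:03d}" for g in range(shared_gene_count)]
    matrices: list[ExpressionMatrix] = []
    for d, spec in enumerate(per_dataset_spec):
        m, _ = generate_planted_matrix(replace(spec, seed=spec.seed))
        values = m.values.copy()
        gene_ids = [f"D{d}-{g}" for g in m.gene_ids]
        row_rng = np.random.default_rng(seed + 7919 * (d + 1))
        for g in range(shared_gene_count):
            values[g] = shared_means[g, d] + row_rng.normal(
                0.0, spec.noise_sd, size=spec.n_samples
            )
            gene_ids[g] = shared_ids[g]
        matrices.append(
            ExpressionMatrix(gene_ids, list(m.sample_ids), values, name=f"disease_{d}")
        )
    return DiseaseCollection(matrices, shared_ids, shared_means)
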