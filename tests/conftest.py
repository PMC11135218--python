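import numpy as np
import pytest

from clustgrid import DistanceMatrix, ExpressionMatrix, PlantedSpec, generate_planted_matrix


@pytest.fixture
def sample_matrix() -> ExpressionMatrix:
    """The 4-gene x 3-timepoint sample microarray grid."""
    return ExpressionMatrix(
        ["Gene 1", "Gene 2", "Gene 3", "Gene 4"],
        ["Time 1", "Time 2", "Time 3"],
        np.array(
            [
                [0.25, 0.22, 0.65],
                [-0.75, 1.25, -0.63],
                [0.05, 0.66, 0.75],
                [1.25, -0.52, 0.15],
            ]
        ),
    )


@pytest.fixture
def three_point_distance() -> DistanceMatrix:
    """1-D points {0, 1, 10} under the Euclidean metric."""
    pts = np.array([0.0, 1.0, 10.0])
    d = np.abs(pts[:, None] - pts[None, :])
    return DistanceMatrix(["P0", "P1", "P2"], d, metric_tag="euclidean")


@pytest.fixture
def planted_small():
    """A clearly separated 40-gene, 12-sample, 3-cluster matrix."""
    return generate_planted_matrix(
        PlantedSpec(n_genes=40, n_samples=12, k=3, separation=10, seed=11)
    )


def random_distance_matrix(rng: np.random.Generator, n: int, integer: bool = False) -> np.ndarray:
    if integer:
        d = rng.integers(1, 6, size=(n, n)).astype(float)
    else:
        d = rng.uniform(0.1, 10.0, size=(n, n))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d
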