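import numpy as np
import pytest

from clustgrid import (
    DistanceMatrix,
    ExpressionMatrix,
    evaluate_grid,
    fitness_score,
    linkage_tree,
    pairwise_distance,
    scan_cut_points,
    silhouette_report,
    within_cluster_distance,
)
from clustgrid.partition import ClusterAssignment
from conftest import random_distance_matrix
from helpers_naive import naive_silhouette, naive_within


def two_pair_setup():
    """1-D points {0, 0.1} vs {10, 10.1} under Euclidean distance."""
    pts = np.array([0.0, 0.1, 10.0, 10.1])
    d = np.abs(pts[:, None] - pts[None, :])
    D = DistanceMatrix(["P0", "P1", "P2", "P3"], d)
    c = ClusterAssignment.from_labels(D.item_ids, [0, 0, 1, 1])
    return D, c


class TestSilhouette:
    def test_two_pair_hand_arithmetic(self):
        D, c = two_pair_setup()
        rep = silhouette_report(D, c)
        # P0: a = 0.1, b = (10 + 10.1)/2 = 10.05
        assert rep.a[0] == pytest.approx(0.1)
        assert rep.b[0] == pytest.approx(10.05)
        assert rep.s[0] == pytest.approx((10.05 - 0.1) / 10.05, abs=1e-9)
        assert rep.s[0] == pytest.approx(0.99005, abs=5e-6)
        assert rep.asw == pytest.approx(0.99000, abs=5e-6)

    def test_all_singletons_rejected(self):
        D, _ = two_pair_setup()
        c = ClusterAssignment.from_labels(D.item_ids, [0, 1, 2, 3])
        with pytest.raises(ValueError, match="silhouette needs"):
            silhouette_report(D, c)

    def test_k1_rejected(self):
        D, _ = two_pair_setup()
        c = ClusterAssignment.from_labels(D.item_ids, [0, 0, 0, 0])
        with pytest.raises(ValueError, match="silhouette needs"):
            silhouette_report(D, c)

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([0.0, 0.1, 10.0])
        d = np.abs(pts[:, None] - pts[None, :])
        D = DistanceMatrix(["P0", "P1", "P2"], d)
        c = ClusterAssignment.from_labels(D.item_ids, [0, 0, 1])
        rep = silhouette_report(D, c)
        assert rep.s[2] == 0.0
        assert rep.asw == pytest.approx(rep.s[:2].mean() * 2 / 3, abs=1e-12)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(40):
            n = int(rng.integers(4, 31))
            d = random_distance_matrix(rng, n)
            k = int(rng.integers(2, n - 1))
            labels = np.concatenate([np.arange(k), rng.integers(0, k, n - k)])
            rng.shuffle(labels)
            c = ClusterAssignment.from_labels([str(i) for i in range(n)], labels)
            rep = silhouette_report(DistanceMatrix(c.item_ids, d), c)
            a, b, s = naive_silhouette(d, c.labels)
            assert np.abs(rep.s - s).max() <= 1e-12
            assert np.abs(rep.a - a).max() <= 1e-12
            assert np.abs(rep.b - b).max() <= 1e-12
            assert -1.0 <= rep.asw <= 1.0


class TestWithinClusterDistance:
    def test_two_cluster_hand_arithmetic(self):
        m = ExpressionMatrix(
            ["a", "b", "c", "d"], ["s"], np.array([[0.0], [2.0], [10.0], [12.0]])
        )
        c = ClusterAssignment.from_labels(m.gene_ids, [0, 0, 1, 1])
        # centroids 1 and 11; every point 1 away
        assert within_cluster_distance(m, c, "euclidean") == pytest.approx(1.0)

    def test_all_singletons_zero(self):
        m = ExpressionMatrix(["a", "b", "c"], ["s"], np.array([[0.0], [5.0], [9.0]]))
        c = ClusterAssignment.from_labels(m.gene_ids, [0, 1, 2])
        assert within_cluster_distance(m, c, "manhattan") == 0.0

    def test_identical_rows_zero(self):
        m = ExpressionMatrix(["a", "b"], ["s1", "s2"], np.array([[1.0, 2.0], [1.0, 2.0]]))
        c = ClusterAssignment.from_labels(m.gene_ids, [0, 0])
        assert within_cluster_distance(m, c, "maximum") == 0.0

    def test_unknown_metric(self):
        m = ExpressionMatrix(["a", "b"], ["s"], np.array([[0.0], [1.0]]))
        c = ClusterAssignment.from_labels(m.gene_ids, [0, 0])
        with pytest.raises(ValueError, match="unknown metric"):
            within_cluster_distance(m, c, "cosine")

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for metric in ("euclidean", "manhattan", "maximum"):
            x = rng.normal(size=(15, 4))
            labels = rng.integers(0, 3, 15)
            labels[:3] = [0, 1, 2]
            m = ExpressionMatrix([str(i) for i in range(15)], list("abcd"), x)
            c = ClusterAssignment.from_labels(m.gene_ids, labels)
            assert within_cluster_distance(m, c, metric) == pytest.approx(
                naive_within(x, c.labels, metric), abs=1e-12
            )


class TestFitnessScore:
    def test_ratio(self):
        assert fitness_score(0.5, 2.0) == 0.25

    def test_zero_silhouette_gives_zero(self):
        assert fitness_score(0.0, 5.0) == 0.0
        assert fitness_score(0.0, 0.0) == 0.0

    def test_monotone_decreasing_in_w(self):
        assert fitness_score(0.8, 1.0) > fitness_score(0.8, 10.0)

    def test_monotone_increasing_in_s(self):
        assert fitness_score(0.9, 2.0) > fitness_score(0.3, 2.0)

    def test_out_of_range_s_rejected(self):
        with pytest.raises(ValueError):
            fitness_score(1.5, 1.0)


class TestScanCutPoints:
    def test_planted_structure_found_at_planted_k(self, planted_small):
        m, truth = planted_small
        D = pairwise_distance(m, "euclidean")
        tree = linkage_tree(D, "average")
        records, best = scan_cut_points(m, D, tree, metric="euclidean")
        assert best.k == 3
        from clustgrid import cut_into_k

        got = cut_into_k(tree, best.k).labels
        # same partition as the planted one
        assert len({(a, b) for a, b in zip(truth.labels, got)}) == 3

    def test_n4_scans_k_2_and_3(self):
        m = ExpressionMatrix(
            ["a", "b", "c", "d"], ["s"], np.array([[0.0], [1.0], [10.0], [11.0]])
        )
        D = pairwise_distance(m, "euclidean")
        tree = linkage_tree(D, "average")
        records, best = scan_cut_points(m, D, tree, metric="euclidean")
        assert [r.k for r in records] == [2, 3]
        assert best.k == 2

    def test_identical_rows_degenerate_no_crash(self):
        m = ExpressionMatrix(
            ["a", "b", "c", "d"], ["s1", "s2"], np.ones((4, 2))
        )
        D = pairwise_distance(m, "euclidean")
        tree = linkage_tree(D, "average")
        records, best = scan_cut_points(m, D, tree, metric="euclidean")
        assert all(r.S == 0 and r.W == 0 and r.F == 0 for r in records)

    def test_too_few_items_rejected(self):
        m = ExpressionMatrix(["a", "b", "c"], ["s"], np.array([[0.0], [1.0], [2.0]]))
        D = pairwise_distance(m, "euclidean")
        tree = linkage_tree(D, "average")
        with pytest.raises(ValueError, match="at least 4"):
            scan_cut_points(m, D, tree)

    def test_k_max_caps_scan(self, planted_small):
        m, _ = planted_small
        D = pairwise_distance(m, "euclidean")
        tree = linkage_tree(D, "average")
        records, _ = scan_cut_points(m, D, tree, k_max=5)
        assert [r.k for r in records] == [2, 3, 4, 5]

    def test_optimal_f_decreases_as_separation_shrinks(self):
        from clustgrid import PlantedSpec, generate_planted_matrix

        means = []
        for sep in (10, 5, 2, 1):
            fs = []
            for seed in range(3):
                m, _ = generate_planted_matrix(
                    PlantedSpec(n_genes=60, n_samples=20, k=3, separation=sep, seed=seed)
                )
                D = pairwise_distance(m, "euclidean")
                tree = linkage_tree(D, "average")
                _, best = scan_cut_points(m, D, tree, metric="euclidean")
                fs.append(best.F)
            means.append(np.mean(fs))
        assert means == sorted(means, reverse=True)


class TestEvaluateGrid:
    def test_default_grid_has_12_cells(self, planted_small):
        m, _ = planted_small
        grid = evaluate_grid(m, k_max=10)
        assert len(grid.records) == 12
        assert {(r.metric, r.linkage) for r in grid.records} == {
            (me, li)
            for me in ("euclidean", "manhattan", "maximum")
            for li in ("single", "complete", "average", "ward")
        }
        assert grid.best.F == max(r.F for r in grid.records)

    def test_single_cell_grid(self, planted_small):
        m, _ = planted_small
        grid = evaluate_grid(m, metrics=["euclidean"], linkages=["ward"], k_max=10)
        assert len(grid.records) == 1
        assert grid.best == grid.records[0]

    def test_empty_lists_rejected(self, planted_small):
        m, _ = planted_small
        with pytest.raises(ValueError):
            evaluate_grid(m, metrics=[], linkages=["ward"])

    def test_grid_deterministic(self, planted_small):
        m, _ = planted_small
        g1 = evaluate_grid(m, k_max=8)
        g2 = evaluate_grid(m, k_max=8)
        assert g1.records == g2.records and g1.best == g2.best
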