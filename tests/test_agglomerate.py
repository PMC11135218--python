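import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from clustgrid import DistanceMatrix, cut_at_height, cut_into_k, linkage_tree
from clustgrid.agglomerate import LINKAGES
from conftest import random_distance_matrix
from helpers_naive import naive_linkage


class TestThreePointHandAgglomeration:
    """1-D points {0, 1, 10}: merges are forced by hand arithmetic."""

    def test_single(self, three_point_distance):
        tree = linkage_tree(three_point_distance, "single")
        assert tree.merges() == [(0, 1, 1.0, 2), (2, 3, 9.0, 3)]

    def test_complete(self, three_point_distance):
        tree = linkage_tree(three_point_distance, "complete")
        assert tree.merges() == [(0, 1, 1.0, 2), (2, 3, 10.0, 3)]

    def test_average(self, three_point_distance):
        tree = linkage_tree(three_point_distance, "average")
        assert tree.merges() == [(0, 1, 1.0, 2), (2, 3, 9.5, 3)]


@pytest.mark.parametrize("method", LINKAGES)
def test_two_items_single_merge_at_their_distance(method):
    D = DistanceMatrix(["a", "b"], np.array([[0.0, 2.5], [2.5, 0.0]]))
    tree = linkage_tree(D, method)
    assert tree.merges() == [(0, 1, 2.5, 2)]


def test_one_item_empty_merge_list():
    D = DistanceMatrix(["a"], np.zeros((1, 1)))
    tree = linkage_tree(D, "average")
    assert tree.n_merges == 0


def test_unknown_method_rejected(three_point_distance):
    with pytest.raises(ValueError, match="unknown linkage"):
        linkage_tree(three_point_distance, "centroid")


class TestOracleEquivalence:
    """Lance-Williams maintenance vs from-scratch recomputation."""

    @pytest.mark.parametrize("method", LINKAGES)
    def test_random_matrices_match_naive_oracle(self, method):
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(3, 16))
            d = random_distance_matrix(rng, n)
            tree = linkage_tree(DistanceMatrix([str(i) for i in range(n)], d), method)
            expected = naive_linkage(d, method)
            for got, exp in zip(tree.merges(), expected):
                assert got[0] == exp[0] and got[1] == exp[1] and got[3] == exp[3]
                assert got[2] == pytest.approx(exp[2], abs=1e-9)

    @pytest.mark.parametrize("method", ["single", "complete"])
    def test_tied_integer_matrices_share_tie_rule_with_oracle(self, method):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(3, 10))
            d = random_distance_matrix(rng, n, integer=True)
            tree = linkage_tree(DistanceMatrix([str(i) for i in range(n)], d), method)
            expected = naive_linkage(d, method)
            assert [(m[0], m[1]) for m in tree.merges()] == [(m[0], m[1]) for m in expected]

    @pytest.mark.parametrize("scipy_method", ["single", "complete", "average"])
    def test_heights_cross_check_against_scipy(self, scipy_method):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 4))
        d = squareform(pdist(x))
        tree = linkage_tree(DistanceMatrix([str(i) for i in range(12)], d), scipy_method)
        z = sch.linkage(pdist(x), method=scipy_method)
        assert np.allclose(np.sort(tree.height), np.sort(z[:, 2]), atol=1e-9)

    def test_ward_on_squared_euclidean_equals_scipy_heights_squared(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 4))
        d = squareform(pdist(x)) ** 2
        tree = linkage_tree(DistanceMatrix([str(i) for i in range(12)], d), "ward")
        z = sch.linkage(pdist(x), method="ward")
        assert np.allclose(np.sort(tree.height), np.sort(z[:, 2] ** 2), atol=1e-8)


@pytest.mark.parametrize("method", LINKAGES)
def test_heights_monotone_nondecreasing(method):
    rng = np.random.default_rng(method.encode()[0])
    for _ in range(20):
        n = int(rng.integers(3, 20))
        d = random_distance_matrix(rng, n)
        tree = linkage_tree(DistanceMatrix([str(i) for i in range(n)], d), method)
        assert (np.diff(tree.height) >= -1e-12).all()


class TestCutting:
    def test_cut_between_merge_heights(self, three_point_distance):
        tree = linkage_tree(three_point_distance, "single")
        a = cut_at_height(tree, 5.0)
        assert a.k == 2
        assert list(a.labels) == [0, 0, 1]

    def test_cut_at_or_above_root_is_one_cluster(self, three_point_distance):
        tree = linkage_tree(three_point_distance, "single")
        assert cut_at_height(tree, 9.0).k == 1
        assert cut_at_height(tree, 100.0).k == 1

    def test_cut_below_first_merge_is_all_singletons(self, three_point_distance):
        tree = linkage_tree(three_point_distance, "single")
        a = cut_at_height(tree, 0.5)
        assert a.k == 3
        assert list(a.labels) == [0, 1, 2]

    def test_cut_into_k_extremes(self, three_point_distance):
        tree = linkage_tree(three_point_distance, "single")
        assert cut_into_k(tree, 1).k == 1
        assert cut_into_k(tree, 3).k == 3
        two = cut_into_k(tree, 2)
        assert list(two.labels) == [0, 0, 1]

    def test_cut_into_k_out_of_range(self, three_point_distance):
        tree = linkage_tree(three_point_distance, "single")
        for bad in (0, 4):
            with pytest.raises(ValueError, match="k must be"):
                cut_into_k(tree, bad)

    def test_cut_into_k_equals_cut_between_heights(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(5, 15))
            d = random_distance_matrix(rng, n)
            tree = linkage_tree(DistanceMatrix([str(i) for i in range(n)], d), "average")
            for k in range(2, n):
                lo, hi = tree.height[n - k - 1], tree.height[n - k]
                if hi - lo <= 1e-12:
                    continue
                h = (lo + hi) / 2
                assert list(cut_into_k(tree, k).labels) == list(cut_at_height(tree, h).labels)
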