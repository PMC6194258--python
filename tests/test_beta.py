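import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from _oracles import brute_weighted_unifrac
from conftest import random_count_vector, tree_from_newick
from gutdiv.beta import (DistanceMatrix, bray_curtis, distance_matrix, nmds,
                         pcoa, weighted_unifrac)
from gutdiv.phylo import BranchMatrix
from gutdiv.simulate import simulate_tree


class TestBrayCurtis:
    @pytest.mark.parametrize("x,y,expected", [
        ([3, 1, 2], [3, 1, 2], 0.0),        # identical samples
        ([5, 0, 0], [0, 3, 2], 1.0),        # disjoint supports
        ([2, 2], [1, 3], 0.25),             # direct formula: 2/8
    ])
    def test_known_values(self, x, y, expected):
        assert bray_curtis(x, y) == pytest.approx(expected)

    def test_all_zero_sample_error(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [1, 2])

    def test_counts_vs_proportions_at_equal_totals(self):
        # on rarefied (equal-total) tables, count and proportion forms agree
        x, y = np.array([10, 30, 60]), np.array([50, 25, 25])
        assert bray_curtis(x, y) == pytest.approx(
            bray_curtis(x / 100, y / 100))


class TestWeightedUnifrac:
    def test_identical_samples_zero(self, bm3):
        x = np.array([3, 1, 2])
        assert weighted_unifrac(x, x, bm3) == pytest.approx(0.0)
        assert weighted_unifrac(x, x, bm3, normalized=False) == \
            pytest.approx(0.0)

    def test_two_leaf_hand_case(self):
        tree = tree_from_newick("(A:1,B:1):0;")
        bm = BranchMatrix(tree, ["A", "B"])
        x, y = np.array([10, 0]), np.array([0, 7])
        assert weighted_unifrac(x, y, bm, normalized=False) == \
            pytest.approx(2.0)
        assert weighted_unifrac(x, y, bm, normalized=True) == \
            pytest.approx(1.0)

    def test_star_tree_l1_limit(self):
        # star tree with unit branches: every branch subtends one leaf, so
        # the raw form collapses to the L1 distance of the p-vectors
        tree = tree_from_newick("(A:1,B:1,C:1,D:1):0;")
        bm = BranchMatrix(tree, ["A", "B", "C", "D"])
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = random_count_vector(rng, 4)
            y = random_count_vector(rng, 4)
            px, py = x / x.sum(), y / y.sum()
            assert weighted_unifrac(x, y, bm, normalized=False) == \
                pytest.approx(np.abs(px - py).sum(), rel=1e-10)

    @pytest.mark.parametrize("normalized", [True, False])
    def test_matches_brute_force_on_random_trees(self, normalized):
        rng = np.random.default_rng(17)
        for n_leaves in (3, 4, 5):
            tree = simulate_tree(n_leaves, seed=int(rng.integers(2 ** 31)))
            leaves = [t.name for t in tree.tips()]
            bm = BranchMatrix(tree, leaves)
            for _ in range(20):
                x = random_count_vector(rng, n_leaves)
                y = random_count_vector(rng, n_leaves)
                expected = brute_weighted_unifrac(
                    dict(zip(leaves, x.tolist())),
                    dict(zip(leaves, y.tolist())), tree,
                    normalized=normalized)
                got = weighted_unifrac(x, y, bm, normalized=normalized)
                assert got == pytest.approx(expected, rel=1e-10, abs=1e-12)

    def test_matches_skbio(self):
        from skbio.diversity import beta_diversity
        rng = np.random.default_rng(23)
        tree = simulate_tree(8, seed=5)
        leaves = [t.name for t in tree.tips()]
        bm = BranchMatrix(tree, leaves)
        counts = np.column_stack([random_count_vector(rng, 8)
                                  for _ in range(4)])
        skbio_d = beta_diversity(
            "weighted_unifrac", counts.T, ids=list("wxyz"),
            taxa=leaves, tree=tree)
        mine = distance_matrix(
            pd.DataFrame(counts, index=leaves, columns=list("wxyz")),
            "weighted_unifrac", bm=bm, normalized=False)
        np.testing.assert_allclose(mine.data, skbio_d.data, rtol=1e-9)

    def test_triangle_inequality_raw_form(self):
        rng = np.random.default_rng(31)
        tree = simulate_tree(6, seed=8)
        leaves = [t.name for t in tree.tips()]
        bm = BranchMatrix(tree, leaves)
        for _ in range(20):
            a, b, c = (random_count_vector(rng, 6) for _ in range(3))
            dab = weighted_unifrac(a, b, bm, normalized=False)
            dbc = weighted_unifrac(b, c, bm, normalized=False)
            dac = weighted_unifrac(a, c, bm, normalized=False)
            assert dac <= dab + dbc + 1e-12


class TestDistanceMatrix:
    def test_identical_samples_zero_matrix(self, bm3):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [1, 2, 3]},
                          index=["A", "B", "C"])
        for metric in ("bray_curtis", "weighted_unifrac"):
            dm = distance_matrix(df, metric, bm=bm3)
            np.testing.assert_allclose(dm.data, 0.0, atol=1e-12)

    def test_entries_equal_pairwise_operation(self, bm3):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            np.column_stack([random_count_vector(rng, 3) for _ in range(5)]),
            index=["A", "B", "C"], columns=list("abcde"))
        bc = distance_matrix(df, "bray_curtis")
        wu = distance_matrix(df, "weighted_unifrac", bm=bm3)
        for i, si in enumerate(df.columns):
            for j, sj in enumerate(df.columns):
                assert bc.data[i, j] == pytest.approx(
                    bray_curtis(df[si], df[sj]) if i != j else 0.0)
                assert wu.data[i, j] == pytest.approx(
                    weighted_unifrac(df[si], df[sj], bm3) if i != j else 0.0)

    def test_sample_permutation_consistency(self, bm3):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            np.column_stack([random_count_vector(rng, 3) for _ in range(4)]),
            index=["A", "B", "C"], columns=list("abcd"))
        dm = distance_matrix(df, "bray_curtis")
        perm = ["c", "a", "d", "b"]
        dm_perm = distance_matrix(df[perm], "bray_curtis")
        idx = [list(df.columns).index(s) for s in perm]
        np.testing.assert_allclose(dm_perm.data, dm.data[np.ix_(idx, idx)])

    def test_symmetry_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(np.array([[0, 1], [2, 0]]), ["a", "b"])


class TestPCoA:
    def test_collinear_points_one_dominant_axis(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(d, list("abcd")))
        assert res.coords.shape[1] == 1
        assert res.neg_coords.shape[1] == 0

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(6, 3))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, [str(i) for i in range(6)]))
        recovered = squareform(pdist(res.coords))
        np.testing.assert_allclose(recovered, d, atol=1e-8)

    def test_equilateral_three_points(self):
        d = np.ones((3, 3)) - np.eye(3)
        res = pcoa(DistanceMatrix(d, list("abc")))
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_negative_eigenvalues_retained_for_non_euclidean(self):
        # Bray-Curtis matrices are generally non-Euclidean
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.integers(0, 50, size=(20, 10)))
        dm = distance_matrix(df, "bray_curtis")
        res = pcoa(dm)
        assert (res.eigenvalues < -1e-10).any()
        assert res.neg_coords.shape[1] == (res.eigenvalues < -1e-10).sum()


class TestNMDS:
    def _euclidean_dm(self, seed=10, n=10, k=2):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, k))
        return DistanceMatrix(squareform(pdist(pts)),
                              [str(i) for i in range(n)])

    def test_embeddable_input_reaches_low_stress(self):
        res = nmds(self._euclidean_dm(), k=2, restarts=4, seed=0)
        assert res.stress < 0.01

    def test_deterministic_given_seed(self):
        dm = self._euclidean_dm(seed=11)
        a = nmds(dm, k=2, restarts=4, seed=3)
        b = nmds(dm, k=2, restarts=4, seed=3)
        np.testing.assert_array_equal(a.coords, b.coords)
        assert a.stress == b.stress

    def test_stress_not_increasing_in_k(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.integers(0, 30, size=(15, 8)))
        dm = distance_matrix(df, "bray_curtis")
        s2 = nmds(dm, k=2, restarts=8, seed=1).stress
        s3 = nmds(dm, k=3, restarts=8, seed=1).stress
        assert s3 <= s2 + 1e-3

    def test_degenerate_equal_distances_warns(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.warns(UserWarning, match="equal"):
            res = nmds(DistanceMatrix(d, list("abcd")), k=2, restarts=2,
                       seed=0)
        assert np.isfinite(res.stress)
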