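"""Beta-diversity metrics and principal coordinates."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

import phylosym as ps
from phylosym.errors import TreeError


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ((3, 1, 2), (3, 1, 2), 0.0),
            ((5, 0, 0), (0, 2, 2), 1.0),
            ((6, 0, 2), (2, 2, 0), 1 - 4 / 12),
        ],
    )
    def test_worked_cases(self, x, y, expected):
        assert ps.bray_curtis(x, y) == pytest.approx(expected)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            x, y = rng.integers(0, 20, 8), rng.integers(0, 20, 8)
            if x.sum() + y.sum() == 0:
                continue
            d = ps.bray_curtis(x, y)
            assert d == ps.bray_curtis(y, x)
            assert 0 <= d <= 1

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            ps.bray_curtis([0, 0], [0, 0])


class TestUniFrac:
    def test_unweighted_worked_case(self):
        tree = ps.read_newick("((A:1,B:1):1,C:2);")
        # unique branches: A(1)+B(1)=2; observed: all 4 branches = 5
        assert ps.unweighted_unifrac({"A", "C"}, {"B", "C"}, tree) == pytest.approx(0.4)

    def test_identical_sets_zero_and_star_disjoint_one(self):
        tree = ps.read_newick("((A:1,B:1):1,C:2);")
        assert ps.unweighted_unifrac({"A", "B"}, {"A", "B"}, tree) == 0.0
        star = ps.read_newick("(A:1,B:1,C:1,D:1);")
        assert ps.unweighted_unifrac({"A", "B"}, {"C", "D"}, star) == 1.0

    def test_presence_only_invariant_to_scaling(self):
        tree = ps.read_newick("((A:1,B:1):1,C:2);")
        d1 = ps.unweighted_unifrac([1, 0, 1], [0, 1, 1], tree, taxa=["A", "B", "C"])
        d2 = ps.unweighted_unifrac([9, 0, 2], [0, 5, 7], tree, taxa=["A", "B", "C"])
        assert d1 == pytest.approx(d2)

    def test_weighted_proportional_samples_zero(self):
        tree = ps.read_newick("((A:1,B:1):1,C:2);")
        d = ps.weighted_unifrac([2, 4, 6], [1, 2, 3], tree, taxa=["A", "B", "C"])
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_weighted_mass_on_distant_leaves_normalized_one(self):
        tree = ps.read_newick("((A:1,B:1):1,C:2);")
        d = ps.weighted_unifrac([1, 0, 0], [0, 0, 1], tree, taxa=["A", "B", "C"], normalized=True)
        assert d == pytest.approx(1.0)

    def test_weighted_three_leaf_hand_case(self):
        # raw weighted UniFrac: sum_b l_b |p_x(b) - p_y(b)|
        # x = all mass on A, y = half A half C:
        # branch A (1): |1-0.5| = .5 ; B (1): 0 ; AB (1): |1-0.5| = .5 ; C (2): |0-0.5|*2 = 1
        tree = ps.read_newick("((A:1,B:1):1,C:2);")
        d = ps.weighted_unifrac([2, 0, 0], [1, 0, 1], tree, taxa=["A", "B", "C"], normalized=False)
        assert d == pytest.approx(2.0)

    def test_agrees_with_skbio_on_random_trees(self, rng):
        from skbio.diversity.beta import unweighted_unifrac as skbio_uu
        from skbio.diversity.beta import weighted_unifrac as skbio_wu

        for seed in range(8):
            tree = ps.simulate_yule_tree(6, 1.0, seed=seed)
            taxa = [t.name for t in tree.tips()]
            x = rng.integers(0, 10, 6)
            y = rng.integers(0, 10, 6)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert ps.unweighted_unifrac(x, y, tree, taxa=taxa) == pytest.approx(
                skbio_uu(x > 0, y > 0, taxa=taxa, tree=tree)
            )
            for norm in (False, True):
                assert ps.weighted_unifrac(x, y, tree, normalized=norm, taxa=taxa) == pytest.approx(
                    skbio_wu(x, y, taxa=taxa, tree=tree, normalized=norm)
                )

    def test_missing_taxon_errors(self):
        tree = ps.read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(TreeError, match="D"):
            ps.unweighted_unifrac({"A", "D"}, {"B"}, tree)

    def test_extra_tree_tips_pruned(self):
        tree = ps.read_newick("(((A:1,B:1):1,C:2):1,Z:5);")
        d = ps.unweighted_unifrac([1, 0, 1], [0, 1, 1], tree, taxa=["A", "B", "C"])
        assert d == pytest.approx(0.4)


class TestPairwise:
    def test_matches_scalar_ops(self, small_table):
        dm = ps.pairwise_distances(small_table, "braycurtis")
        for i, a in enumerate(small_table.sample_ids):
            for j, b in enumerate(small_table.sample_ids):
                if i < j:
                    expected = ps.bray_curtis(
                        small_table.counts[a], small_table.counts[b]
                    )
                    assert dm[a, b] == pytest.approx(expected)

    def test_single_sample_zero_matrix(self, small_table):
        t = ps.OtuTable(small_table.counts[["s1"]])
        dm = ps.pairwise_distances(t, "braycurtis")
        assert dm.shape == (1, 1) and dm.data[0, 0] == 0

    def test_column_permutation_consistency(self, small_table):
        dm1 = ps.pairwise_distances(small_table, "braycurtis")
        t2 = ps.OtuTable(small_table.counts[["s3", "s1", "s4", "s2"]])
        dm2 = ps.pairwise_distances(t2, "braycurtis")
        for a in small_table.sample_ids:
            for b in small_table.sample_ids:
                assert dm1[a, b] == pytest.approx(dm2[a, b])

    def test_unifrac_requires_tree(self, small_table):
        with pytest.raises(ValueError, match="tree"):
            ps.pairwise_distances(small_table, "unifrac")


class TestPcoa:
    def test_zero_matrix_gives_zero_coordinates(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        res = ps.pcoa(dm)
        np.testing.assert_allclose(res.coordinates.to_numpy(), 0.0, atol=1e-12)

    def test_collinear_points_single_positive_eigenvalue(self):
        dm = DistanceMatrix([[0, 1, 2], [1, 0, 1], [2, 1, 0]], ids=list("abc"))
        res = ps.pcoa(dm)
        assert np.sum(res.eigenvalues > 1e-9) == 1
        coords = res.coordinates.to_numpy()
        from scipy.spatial.distance import pdist, squareform

        np.testing.assert_allclose(squareform(pdist(coords)), dm.data, atol=1e-9)

    def test_planar_cloud_two_positive_eigenvalues(self, rng):
        pts = rng.random((6, 2))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(6)])
        res = ps.pcoa(dm)
        assert np.sum(res.eigenvalues > 1e-9) == 2
        np.testing.assert_allclose(
            squareform(pdist(res.coordinates.to_numpy())), dm.data, atol=1e-9
        )
        assert res.proportion_explained[:2].sum() == pytest.approx(1.0)

    def test_negative_eigenvalues_reported_untouched(self, small_table):
        dm = ps.pairwise_distances(small_table, "braycurtis")
        res = ps.pcoa(dm)
        assert res.negative_axes.any() == (res.eigenvalues.min() < 0)
        assert list(res.eigenvalues) == sorted(res.eigenvalues, reverse=True)

    def test_agrees_with_skbio_on_euclidean_input(self, rng):
        from skbio.stats.ordination import pcoa as skbio_pcoa
        from scipy.spatial.distance import pdist, squareform

        pts = rng.random((5, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(5)])
        ours = ps.pcoa(dm)
        theirs = skbio_pcoa(dm, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()[:, :3]),
            np.abs(theirs.samples.to_numpy()),
            atol=1e-8,
        )
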