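"""Cluster extraction, UPGMA, RF/MC distances, random topologies, congruence."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from skbio import DistanceMatrix

import phylosym as ps
from phylosym.errors import TreeError
from phylosym.trees import _grow_tree, _sample_masks, _choice_bounds, _leaf_positions, _cluster_masks


def clusters_of(tree):
    return ps.extract_clusters(tree)


def mc_bruteforce(c1, c2):
    """Factorial-enumeration oracle for the Matching Cluster distance."""
    a, b = list(c1), list(c2)
    k = max(len(a), len(b))
    a += [frozenset()] * (k - len(a))
    b += [frozenset()] * (k - len(b))
    best = None
    for perm in itertools.permutations(range(k)):
        cost = sum(len(a[i] ^ b[perm[i]]) for i in range(k))
        if best is None or cost < best:
            best = cost
    return best or 0


class TestClusters:
    @pytest.mark.parametrize(
        "newick,expected",
        [
            ("((A,B),(C,D));", {frozenset("AB"), frozenset("CD")}),
            ("(((A,B),C),D);", {frozenset("AB"), frozenset("ABC")}),
            ("(A,B);", set()),
        ],
    )
    def test_examples(self, newick, expected):
        assert clusters_of(ps.read_newick(newick)) == frozenset(expected)

    def test_bifurcating_tree_has_n_minus_2_clusters(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            t = ps.random_topology([f"L{i}" for i in range(n)], rng)
            assert len(clusters_of(t)) == n - 2

    def test_laminar_family(self, rng):
        t = ps.random_topology([f"L{i}" for i in range(8)], rng)
        cl = list(clusters_of(t))
        for a, b in itertools.combinations(cl, 2):
            assert a <= b or b <= a or not (a & b)


class TestUpgma:
    def test_three_leaf_worked_case(self):
        dm = DistanceMatrix([[0, 2, 6], [2, 0, 6], [6, 6, 0]], ids=list("ABC"))
        tree = ps.upgma(dm)
        assert clusters_of(tree) == frozenset({frozenset("AB")})
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}
        (ab_node,) = [n for n in tree.non_tips()]
        assert ab_node.length == 2.0

    def test_two_labels_cherry_at_half_distance(self):
        dm = DistanceMatrix([[0, 3.0], [3.0, 0]], ids=["x", "y"])
        tree = ps.upgma(dm)
        assert {t.length for t in tree.tips()} == {1.5}

    def test_recovers_random_ultrametric_trees(self, rng):
        for seed in range(20):
            true = ps.simulate_yule_tree(int(rng.integers(4, 9)), 1.0, seed)
            tips = list(true.tips())
            ids = [t.name for t in tips]
            data = np.zeros((len(ids), len(ids)))
            for i, a in enumerate(tips):
                for j, b in enumerate(tips):
                    if i < j:
                        data[i, j] = data[j, i] = a.distance(b)
            rebuilt = ps.upgma(DistanceMatrix(data, ids=ids))
            assert clusters_of(rebuilt) == clusters_of(true)

    def test_agrees_with_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        for _ in range(10):
            n = 6
            x = rng.random((n, 4))
            from scipy.spatial.distance import pdist

            d = pdist(x)
            tree = ps.upgma(DistanceMatrix(squareform(d), ids=[f"s{i}" for i in range(n)]))
            merge_heights = sorted(
                round(h, 10)
                for h in {
                    _height(node) for node in tree.non_tips(include_self=True)
                }
            )
            scipy_heights = sorted(round(h / 2, 10) for h in average(d)[:, 2])
            assert merge_heights == pytest.approx(scipy_heights)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            ps.upgma(np.array([[0, np.nan], [np.nan, 0]]))


def _height(node):
    h = 0.0
    cur = node
    while cur.children:
        cur = cur.children[0]
        h += cur.length
    return h


class TestDistances:
    def test_rf_examples(self):
        t1, t2 = ps.read_newick("((A,B),C);"), ps.read_newick("((A,C),B);")
        assert ps.rf_distance(t1, t1) == 0
        assert ps.rf_distance(t1, t2) == 2
        cat, bal = ps.read_newick("(((A,B),C),D);"), ps.read_newick("((A,B),(C,D));")
        assert ps.rf_distance(cat, bal) == 2

    def test_mc_examples(self):
        cat, bal = ps.read_newick("(((A,B),C),D);"), ps.read_newick("((A,B),(C,D));")
        assert ps.matching_cluster_distance(cat, cat) == 0
        assert ps.matching_cluster_distance(cat, bal) == 3

    def test_leaf_set_mismatch_lists_difference(self):
        t1, t2 = ps.read_newick("((A,B),C);"), ps.read_newick("((A,B),D);")
        with pytest.raises(TreeError, match="C"):
            ps.rf_distance(t1, t2)

    @given(st.integers(0, 10_000))
    def test_metric_properties_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        labels = [f"L{i}" for i in range(n)]
        t1, t2 = ps.random_topology(labels, rng), ps.random_topology(labels, rng)
        rf, mc = ps.rf_distance(t1, t2), ps.matching_cluster_distance(t1, t2)
        assert rf >= 0 and mc >= 0
        assert rf == ps.rf_distance(t2, t1)
        assert mc == ps.matching_cluster_distance(t2, t1)
        same = clusters_of(t1) == clusters_of(t2)
        assert (rf == 0) == same
        assert (mc == 0) == same
        assert mc == mc_bruteforce(clusters_of(t1), clusters_of(t2))

    def test_triangle_inequality_all_5_leaf_triples(self):
        trees = list(ps.enumerate_topologies(list("ABCDE")))[:35]
        pre = [(clusters_of(t), t) for t in trees]
        import random

        random.seed(0)
        for _ in range(300):
            a, b, c = random.sample(pre, 3)
            for dist in (ps.rf_distance, ps.matching_cluster_distance):
                assert dist(a[1], c[1]) <= dist(a[1], b[1]) + dist(b[1], c[1])

    def test_mc_more_graded_than_rf_on_5_leaves(self):
        trees = list(ps.enumerate_topologies(list("ABCDE")))
        pos = _leaf_positions(trees[0])
        masks = [sorted(_cluster_masks(t, pos)) for t in trees]
        from phylosym.trees import _mc_from_masks

        rf_vals, mc_vals = set(), set()
        for i, j in itertools.combinations(range(len(trees)), 2):
            rf_vals.add(len(set(masks[i]) ^ set(masks[j])))
            mc_vals.add(_mc_from_masks(masks[i], masks[j]))
        assert len(mc_vals) >= len(rf_vals)

    def test_multifurcating_trees_accepted(self):
        star = ps.read_newick("(A,B,C,D);")
        cat = ps.read_newick("(((A,B),C),D);")
        assert ps.rf_distance(star, cat) == 2  # star has no clusters
        assert ps.matching_cluster_distance(star, cat) == 5


class TestNormalization:
    @pytest.mark.parametrize("n,expected", [(4, 4.0), (5, 6.0)])
    def test_rf_closed_form(self, n, expected):
        assert ps.normalization_constant("rf", n_leaves=n).value == expected

    def test_mc_enumerated_max_is_definitional(self):
        cat5 = ps.read_newick("((((A,B),C),D),E);")
        const = ps.normalization_constant("mc", reference_tree=cat5)
        assert const.mode == "enumerated"
        worst = max(
            ps.matching_cluster_distance(cat5, t)
            for t in ps.enumerate_topologies(list("ABCDE"))
        )
        assert const.value == worst

    def test_mc_null_max_mode_for_large_trees(self, rng):
        labels = [f"L{i}" for i in range(10)]
        ref = ps.random_topology(labels, rng)
        null = ps.null_distance_sample(ref, "mc", 500, rng)
        const = ps.normalization_constant("mc", reference_tree=ref, null_distances=null)
        assert const.mode == "null-max" and const.value == null.max()


class TestRandomTopology:
    def test_two_leaves_always_the_cherry(self, rng):
        for _ in range(5):
            t = ps.random_topology(["a", "b"], rng)
            assert {x.name for x in t.tips()} == {"a", "b"} and not clusters_of(t)

    def test_three_leaf_uniformity(self, rng):
        from collections import Counter
        from scipy.stats import chisquare

        counts = Counter()
        for _ in range(30_000):
            t = ps.random_topology(list("ABC"), rng)
            (cherry,) = clusters_of(t) or [frozenset("ABC")]
            counts[cherry] += 1
        # n=3: the cherry identifies the topology; 3 equally likely
        assert len(counts) == 3
        assert chisquare(list(counts.values())).pvalue > 0.001

    def test_enumeration_count_matches_double_factorial(self):
        assert ps.n_topologies(4) == 15 and ps.n_topologies(5) == 105
        assert len({frozenset(clusters_of(t)) for t in ps.enumerate_topologies(list("ABCD"))}) == 15

    def test_fast_sampler_matches_tree_growth(self, rng):
        # the bitmask null sampler and the TreeNode builder share choice
        # semantics: identical cluster sets for identical choice vectors
        for _ in range(50):
            n = int(rng.integers(3, 9))
            labels = sorted(f"L{i:02d}" for i in range(n))
            choices = [int(rng.integers(0, b)) for b in _choice_bounds(n)]
            tree = _grow_tree(labels, choices)
            pos = {lab: i for i, lab in enumerate(labels)}
            assert set(_cluster_masks(tree, pos)) == set(_sample_masks(n, choices))


class TestCongruenceTest:
    def test_identical_four_leaf_p_near_one_fifteenth(self):
        t = ps.read_newick("((A,B),(C,D));")
        res = ps.congruence_test(t, t, "rf", n_random=30_000, seed=42)
        assert res.raw == 0 and res.normalized == 0.0
        assert res.p_value == pytest.approx(1 / 15, abs=0.006)

    def test_maximally_distant_pair_p_one(self):
        t1 = ps.read_newick("(((A,B),C),D);")  # clusters {AB},{ABC}
        t2 = ps.read_newick("(((C,D),B),A);")  # clusters {CD},{BCD}
        assert ps.rf_distance(t1, t2) == 4  # the n=4 maximum
        res = ps.congruence_test(t1, t2, "rf", n_random=2000, seed=0)
        assert res.p_value == 1.0 and res.normalized == 1.0

    def test_deterministic_given_seed(self, host6):
        d = ps.random_topology([t.name for t in host6.tips()], 7)
        r1 = ps.congruence_test(host6, d, "mc", n_random=2000, seed=5)
        r2 = ps.congruence_test(host6, d, "mc", n_random=2000, seed=5)
        assert r1 == r2

    def test_plus_one_estimator_never_zero(self, host6):
        res = ps.congruence_test(host6, host6, "rf", n_random=50, seed=1, plus_one=True)
        assert res.p_value >= 1 / 51

    def test_null_summary_and_bounds(self, host6):
        d = ps.random_topology([t.name for t in host6.tips()], 3)
        res = ps.congruence_test(host6, d, "rf", n_random=1000, seed=2)
        assert 0 <= res.null_min <= res.null_median <= res.null_max <= 1.0
        assert 0 <= res.normalized <= 1.0 and 0 <= res.p_value <= 1.0

    def test_too_few_leaves_rejected(self):
        t = ps.read_newick("(A,B);")
        with pytest.raises(TreeError):
            ps.congruence_test(t, t, "rf", n_random=10, seed=0)

    def test_randomized_pvalue_uniform_under_exchangeability(self, rng):
        # draw observed from the same distribution as the null: exact U(0,1)
        ps_vals = []
        null = rng.integers(0, 5, size=400)
        for _ in range(500):
            obs = rng.integers(0, 5)
            ps_vals.append(ps.randomized_null_pvalue(obs, null, rng))
        from scipy.stats import kstest

        assert kstest(ps_vals, "uniform").pvalue > 0.001
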