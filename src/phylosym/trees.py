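"""Rooted-tree topology metrics and the random-topology congruence test.

This is the heart of the phylosymbiosis analysis. A rooted tree on a leaf
set induces a family of *clusters* (the leaf subsets below its internal
nodes). Two topology distances are defined on these cluster families:

* **Robinson-Foulds (RF)**: the size of the symmetric difference between the
  two cluster sets. For rooted bifurcating trees on ``n`` leaves its maximum
  is ``2(n - 2)``.
* **Matching Cluster (MC)**: the minimum total cost of a perfect matching
  between the two cluster sets (padded with empty pseudo-clusters), where
  matching cluster ``c1`` to ``c2`` costs ``|c1 symdiff c2|`` and matching a
  cluster to the empty pseudo-cluster costs its size. MC degrades gracefully
  under small local rearrangements where RF jumps.

Significance of an observed host-tree/dendrogram distance is assessed
against a null of uniformly random labelled rooted bifurcating topologies on
the same leaves, generated by stepwise addition: each successive leaf is
attached to an edge chosen uniformly among all current edges (including the
root edge), which yields each of the ``(2n-3)!!`` topologies with equal
probability.

Clusters here are *nontrivial proper* clusters: singletons and the full leaf
set (the root) are excluded. With this convention RF = 0 (and MC = 0) exactly
when the two rooted topologies are identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from typing import Iterator, NamedTuple, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from skbio import DistanceMatrix, TreeNode

from .errors import TreeError

__all__ = [
    "extract_clusters",
    "upgma",
    "rf_distance",
    "matching_cluster_distance",
    "normalization_constant",
    "NormalizationConstant",
    "random_topology",
    "enumerate_topologies",
    "n_topologies",
    "congruence_test",
    "CongruenceResult",
    "null_distance_sample",
    "randomized_null_pvalue",
]


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------


def extract_clusters(tree: TreeNode) -> frozenset[frozenset[str]]:
    """The nontrivial proper clusters of a rooted tree.

    One cluster (a frozenset of leaf labels) per internal node, excluding
    the root and any cluster of size < 2 or equal to the whole leaf set.
    """
    leaves = [t.name for t in tree.tips()]
    n = len(leaves)
    clusters = set()
    for node in tree.non_tips(include_self=False):
        c = frozenset(t.name for t in node.tips())
        if 2 <= len(c) < n:
            clusters.add(c)
    return frozenset(clusters)


def _leaf_positions(tree: TreeNode) -> dict[str, int]:
    names = sorted(t.name for t in tree.tips())
    dup = [n for i, n in enumerate(names) if i and names[i - 1] == n]
    if dup:
        raise TreeError(f"duplicate leaf label {dup[0]!r}")
    return {name: i for i, name in enumerate(names)}


def _cluster_masks(tree: TreeNode, pos: dict[str, int]) -> set[int]:
    """Clusters of ``tree`` encoded as bitmasks over the leaf ordering ``pos``."""
    n = len(pos)
    full = (1 << n) - 1
    masks: dict[int, int] = {}
    out: set[int] = set()
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            try:
                masks[id(node)] = 1 << pos[node.name]
            except KeyError:
                raise TreeError(f"leaf {node.name!r} not in the shared leaf set") from None
        else:
            m = 0
            for child in node.children:
                m |= masks[id(child)]
            masks[id(node)] = m
            if node.parent is not None and m != full and bin(m).count("1") >= 2:
                out.add(m)
    return out


def _check_same_leaves(t1: TreeNode, t2: TreeNode) -> dict[str, int]:
    pos = _leaf_positions(t1)
    names2 = {t.name for t in t2.tips()}
    if set(pos) != names2:
        only1 = sorted(set(pos) - names2)
        only2 = sorted(names2 - set(pos))
        raise TreeError(
            f"leaf sets differ; only in first: {only1 or '-'}, only in second: {only2 or '-'}"
        )
    return pos


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomerative clustering of a distance matrix.

    Clusters merge at height ``d/2`` (so an ultrametric input is recovered
    exactly); branch lengths are height differences. Ties between equally
    close pairs are broken by the lexicographically smallest pair of member
    labels, making the output deterministic.
    """
    if not isinstance(dm, DistanceMatrix):
        arr = np.asarray(dm, dtype=float)
        if np.isnan(arr).any():
            raise ValueError("distance matrix contains NaN")
        dm = DistanceMatrix(arr)
    if np.isnan(dm.data).any():
        raise ValueError("distance matrix contains NaN")
    labels = list(dm.ids)
    if len(labels) < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    # active clusters: key -> (min member label, node, height, size)
    nodes: dict[int, TreeNode] = {}
    heights: dict[int, float] = {}
    sizes: dict[int, int] = {}
    minlab: dict[int, str] = {}
    dist: dict[tuple[int, int], float] = {}
    for i, lab in enumerate(labels):
        nodes[i] = TreeNode(name=lab)
        heights[i] = 0.0
        sizes[i] = 1
        minlab[i] = lab
    active = list(range(len(labels)))
    for i, j in itertools.combinations(range(len(labels)), 2):
        dist[(i, j)] = float(dm.data[i, j])
    next_id = len(labels)
    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(active, 2):
            d = dist[(min(i, j), max(i, j))]
            key = (d, tuple(sorted((minlab[i], minlab[j]))))
            if best is None or key < best[0]:
                best = (key, i, j)
        (_, _), i, j = (best[0], best[1], best[2])
        d_ij = dist[(min(i, j), max(i, j))]
        h = d_ij / 2.0
        parent = TreeNode()
        for child_id in sorted((i, j), key=lambda c: minlab[c]):
            child = nodes[child_id]
            child.length = max(h - heights[child_id], 0.0)
            parent.append(child)
        nodes[next_id] = parent
        heights[next_id] = h
        sizes[next_id] = sizes[i] + sizes[j]
        minlab[next_id] = min(minlab[i], minlab[j])
        for k in active:
            if k in (i, j):
                continue
            d_ik = dist[(min(i, k), max(i, k))]
            d_jk = dist[(min(j, k), max(j, k))]
            d_new = (sizes[i] * d_ik + sizes[j] * d_jk) / (sizes[i] + sizes[j])
            dist[(min(next_id, k), max(next_id, k))] = d_new
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    root = nodes[active[0]]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Rooted Robinson-Foulds distance: |symmetric difference of cluster sets|."""
    pos = _check_same_leaves(t1, t2)
    return len(_cluster_masks(t1, pos) ^ _cluster_masks(t2, pos))


def _mc_from_masks(masks1: Sequence[int], masks2: Sequence[int]) -> int:
    k = max(len(masks1), len(masks2))
    if k == 0:
        return 0
    a = list(masks1) + [0] * (k - len(masks1))
    b = list(masks2) + [0] * (k - len(masks2))
    cost = np.empty((k, k), dtype=np.int64)
    for i, m1 in enumerate(a):
        for j, m2 in enumerate(b):
            cost[i, j] = bin(m1 ^ m2).count("1")
    rows, cols = linear_sum_assignment(cost)
    return int(cost[rows, cols].sum())


def matching_cluster_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Matching Cluster distance, solved exactly via the assignment problem.

    The two cluster sets are padded with empty pseudo-clusters to equal
    size; matching ``c1`` to ``c2`` costs ``|c1 symdiff c2|`` and matching a
    cluster to an empty pseudo-cluster costs its size.
    """
    pos = _check_same_leaves(t1, t2)
    return _mc_from_masks(sorted(_cluster_masks(t1, pos)), sorted(_cluster_masks(t2, pos)))


# ---------------------------------------------------------------------------
# Topology generation (stepwise addition)
# ---------------------------------------------------------------------------


def n_topologies(n: int) -> int:
    """Number of labelled rooted bifurcating topologies on n leaves: (2n-3)!!."""
    if n < 2:
        raise ValueError("need at least 2 leaves")
    out = 1
    for k in range(3, n + 1):
        out *= 2 * k - 3
    return out


def _choice_bounds(n: int) -> list[int]:
    """Edge-count bound when attaching leaf k (0-based index 2..n-1)."""
    return [2 * k - 1 for k in range(2, n)]


def _grow_tree(labels: Sequence[str], choices: Sequence[int]) -> TreeNode:
    """Build a rooted bifurcating tree by stepwise addition.

    ``choices[k-2]`` selects the attachment edge for ``labels[k]`` among the
    current non-root nodes (in creation order) plus, as the last index, the
    root edge (a new root above everything).
    """
    root = TreeNode()
    first, second = TreeNode(name=labels[0]), TreeNode(name=labels[1])
    root.append(first)
    root.append(second)
    edges = [first, second]  # every non-root node defines the edge above it
    for label, c in zip(labels[2:], choices):
        leaf = TreeNode(name=label)
        if c == len(edges):
            new_root = TreeNode()
            new_root.append(root)
            edges.append(root)
            new_root.append(leaf)
            root = new_root
        else:
            u = edges[c]
            parent = u.parent
            parent.remove(u)
            v = TreeNode()
            v.append(u)
            v.append(leaf)
            parent.append(v)
            edges.append(v)
        edges.append(leaf)
    return root


def random_topology(leaf_labels: Sequence[str], rng: np.random.Generator | int | None = None) -> TreeNode:
    """Draw a uniformly random labelled rooted bifurcating topology.

    Uniformity over all ``(2n-3)!!`` topologies follows from stepwise
    addition with a uniform edge choice (root edge included) at every step.
    The returned tree carries no branch lengths.
    """
    if len(leaf_labels) < 2:
        raise TreeError("need at least 2 leaf labels")
    if len(set(leaf_labels)) != len(leaf_labels):
        raise TreeError("leaf labels must be unique")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    choices = [int(rng.integers(0, b)) for b in _choice_bounds(len(leaf_labels))]
    return _grow_tree(leaf_labels, choices)


def enumerate_topologies(leaf_labels: Sequence[str]) -> Iterator[TreeNode]:
    """Yield every labelled rooted bifurcating topology on ``leaf_labels``.

    There are ``(2n-3)!!`` of them; enumeration is by exhausting all
    stepwise-addition choice vectors (a bijection onto topologies).
    """
    bounds = _choice_bounds(len(leaf_labels))
    for choices in itertools.product(*(range(b) for b in bounds)):
        yield _grow_tree(leaf_labels, choices)


# Fast bitmask-only growth used for large null samples: same stepwise
# addition as _grow_tree but never materializes TreeNode objects.


def _sample_masks(n: int, choices: Sequence[int]) -> list[int]:
    parent = [-1] * (2 * n)  # node ids; leaves 0..n-1, internals from n
    mask = [0] * (2 * n)
    for i in range(n):
        mask[i] = 1 << i
    root = n
    parent[0] = parent[1] = root
    mask[root] = 0b11
    edges = [0, 1]
    internals = []
    next_id = n + 1
    for k in range(2, n):
        c = choices[k - 2]
        v = next_id
        next_id += 1
        leafbit = 1 << k
        if c == len(edges):
            mask[v] = mask[root] | leafbit
            parent[root] = v
            parent[k] = v
            parent[v] = -1
            edges.append(root)
            internals.append(root)
            root = v
        else:
            u = edges[c]
            mask[v] = mask[u] | leafbit
            p = parent[u]
            parent[v] = p
            parent[u] = v
            parent[k] = v
            w = p
            while w != -1:
                mask[w] |= leafbit
                w = parent[w]
            edges.append(v)
            internals.append(v)
        edges.append(k)
    return [mask[v] for v in internals]


def _sample_masks_batch(n: int, n_draws: int, rng: np.random.Generator) -> Iterator[list[int]]:
    bounds = _choice_bounds(n)
    cols = [rng.integers(0, b, size=n_draws) for b in bounds]
    for i in range(n_draws):
        yield _sample_masks(n, [int(col[i]) for col in cols])


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

#: Leaf counts up to which the MC normalization maximum is found by
#: exhaustive enumeration of all topologies; beyond this the maximum over
#: the sampled null is used instead.
MC_ENUMERATION_LIMIT = 8


class NormalizationConstant(NamedTuple):
    value: float
    mode: str  # 'formula' (RF), 'enumerated' or 'null-max' (MC)


def normalization_constant(
    metric: str,
    reference_tree: TreeNode | None = None,
    n_leaves: int | None = None,
    null_distances: np.ndarray | None = None,
) -> NormalizationConstant:
    """Constant by which a raw tree distance is divided to land in [0, 1].

    RF: the closed form ``2(n - 2)``, the maximal symmetric difference
    between two rooted bifurcating trees on ``n`` leaves.

    MC: the maximum MC distance from ``reference_tree`` to any rooted
    bifurcating topology on the same leaves -- found by exhaustive
    enumeration for ``n <= 8`` (at most 135,135 topologies) and otherwise as
    the maximum over the supplied null sample. ``mode`` records which route
    was taken.
    """
    metric = metric.lower()
    if metric == "rf":
        if n_leaves is None:
            if reference_tree is None:
                raise ValueError("RF normalization needs n_leaves or a reference tree")
            n_leaves = sum(1 for _ in reference_tree.tips())
        if n_leaves < 3:
            raise TreeError("RF normalization requires at least 3 leaves")
        return NormalizationConstant(float(2 * (n_leaves - 2)), "formula")
    if metric != "mc":
        raise ValueError(f"unknown metric {metric!r}; choose 'rf' or 'mc'")
    if reference_tree is None:
        raise ValueError("MC normalization needs the reference tree")
    pos = _leaf_positions(reference_tree)
    n = len(pos)
    if n < 3:
        raise TreeError("MC normalization requires at least 3 leaves")
    ref_masks = sorted(_cluster_masks(reference_tree, pos))
    if n <= MC_ENUMERATION_LIMIT:
        best = 0
        for choices in itertools.product(*(range(b) for b in _choice_bounds(n))):
            d = _mc_from_masks(ref_masks, sorted(_sample_masks(n, choices)))
            if d > best:
                best = d
        return NormalizationConstant(float(best), "enumerated")
    if null_distances is None or len(null_distances) == 0:
        raise ValueError(
            f"MC normalization for n > {MC_ENUMERATION_LIMIT} needs a sampled null"
        )
    return NormalizationConstant(float(np.max(null_distances)), "null-max")


# ---------------------------------------------------------------------------
# Congruence test
# ---------------------------------------------------------------------------


@dataclass
class CongruenceResult:
    """Outcome of comparing a microbiota dendrogram to a host phylogeny."""

    metric: str
    raw: int
    normalization: float
    normalization_mode: str
    normalized: float
    p_value: float
    n_random: int
    null_min: float
    null_median: float
    null_max: float
    seed: int | None

    def to_dict(self) -> dict:
        return asdict(self)


def null_distance_sample(
    reference_tree: TreeNode,
    metric: str = "rf",
    n_random: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Raw distances from ``reference_tree`` to ``n_random`` uniformly random
    rooted bifurcating topologies on the same leaves."""
    metric = metric.lower()
    pos = _leaf_positions(reference_tree)
    n = len(pos)
    if n < 3:
        raise TreeError("the null has no topology variation below 3 leaves")
    ref = _cluster_masks(reference_tree, pos)
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = np.empty(n_random, dtype=np.int64)
    if metric == "rf":
        ref_set = ref
        n_ref = len(ref_set)
        for i, masks in enumerate(_sample_masks_batch(n, n_random, rng)):
            overlap = sum(1 for m in masks if m in ref_set)
            out[i] = (n_ref - overlap) + (len(masks) - overlap)
    elif metric == "mc":
        ref_sorted = sorted(ref)
        for i, masks in enumerate(_sample_masks_batch(n, n_random, rng)):
            out[i] = _mc_from_masks(ref_sorted, sorted(masks))
    else:
        raise ValueError(f"unknown metric {metric!r}; choose 'rf' or 'mc'")
    return out


def congruence_test(
    host_tree: TreeNode,
    dendrogram: TreeNode,
    metric: str = "rf",
    n_random: int = 100_000,
    seed: int | None = None,
    plus_one: bool = False,
    norm_constant: NormalizationConstant | None = None,
) -> CongruenceResult:
    """Topological congruence of a microbiota dendrogram with a host phylogeny.

    Computes the observed RF or MC distance, samples ``n_random`` uniformly
    random rooted bifurcating topologies on the same leaves, and reports

        p = #(random distance <= observed) / n_random

    i.e. the probability that stochastic assembly alone yields an equally or
    more congruent dendrogram. ``plus_one=True`` switches to the never-zero
    estimator ``(k + 1) / (n_random + 1)``. The normalized score divides the
    raw distance by the metric's normalization constant (which may be
    supplied precomputed via ``norm_constant`` to amortize the MC
    enumeration across repeated calls against the same host tree).
    """
    metric = metric.lower()
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    pos = _check_same_leaves(host_tree, dendrogram)
    n = len(pos)
    if n < 3:
        raise TreeError("congruence testing needs at least 3 leaves")
    host_masks = _cluster_masks(host_tree, pos)
    dend_masks = _cluster_masks(dendrogram, pos)
    if metric == "rf":
        observed = len(host_masks ^ dend_masks)
    elif metric == "mc":
        observed = _mc_from_masks(sorted(host_masks), sorted(dend_masks))
    else:
        raise ValueError(f"unknown metric {metric!r}; choose 'rf' or 'mc'")
    rng = np.random.default_rng(seed)
    null = null_distance_sample(host_tree, metric, n_random, rng)
    k = int(np.sum(null <= observed))
    p = (k + 1) / (n_random + 1) if plus_one else k / n_random
    if norm_constant is None:
        norm_constant = normalization_constant(
            metric, reference_tree=host_tree, n_leaves=n, null_distances=null
        )
    const = norm_constant.value
    null_norm = null / const if const > 0 else null.astype(float)
    return CongruenceResult(
        metric=metric,
        raw=int(observed),
        normalization=const,
        normalization_mode=norm_constant.mode,
        normalized=float(observed / const) if const > 0 else 0.0,
        p_value=float(p),
        n_random=int(n_random),
        null_min=float(null_norm.min()),
        null_median=float(np.median(null_norm)),
        null_max=float(null_norm.max()),
        seed=seed,
    )


def randomized_null_pvalue(
    observed: float, null: np.ndarray, rng: np.random.Generator | int | None = None
) -> float:
    """Tie-randomized permutation p-value.

    Tree distances are integer-valued, so the plain estimator
    ``#(null <= observed) / n`` takes only a handful of values and cannot be
    uniform. Randomly splitting ties,

        p = (#(null < observed) + V * (1 + #(null == observed))) / (n + 1)

    with ``V ~ Uniform(0, 1)``, is exactly uniform on (0, 1) whenever the
    observed value is exchangeable with the null draws -- the appropriate
    calibration check for a discrete test statistic.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    null = np.asarray(null)
    less = int(np.sum(null < observed))
    ties = int(np.sum(null == observed))
    return (less + rng.uniform() * (1 + ties)) / (len(null) + 1)
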