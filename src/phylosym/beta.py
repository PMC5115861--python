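"""Pairwise community dissimilarity and principal coordinates.

Bray-Curtis is implemented directly from its definition. The phylogenetic
UniFrac metrics walk the OTU tree's branches once per pair: unweighted
UniFrac is the branch length leading exclusively to one sample's taxa over
the branch length leading to either sample's taxa; weighted UniFrac sums
branch lengths times absolute differences in descending count proportions,
optionally normalized by the maximal value attainable given the tree and
the two samples' tip proportions (so the result is bounded by 1). Both
accept trees with multifurcations, including star trees; tree tips without
counts simply never contribute. Principal coordinates analysis is classical metric
scaling: double-center ``-D**2/2``, eigendecompose, and scale eigenvectors by
the square roots of positive eigenvalues. Negative eigenvalues (from
non-Euclidean dissimilarities like Bray-Curtis) are reported untouched and
their axes flagged rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .errors import TreeError
from .io import OtuTable

__all__ = [
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pairwise_distances",
    "pcoa",
    "PcoaResult",
]


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity ``1 - 2 sum(min(x, y)) / (sum(x) + sum(y))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("Bray-Curtis is undefined when both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def _tree_branches(tree: TreeNode, taxa: list[str]):
    """UniFrac geometry of ``tree`` restricted to ``taxa``.

    Returns ``(branches, tip_depths)`` where ``branches`` is a list of
    (length, tip-index list) pairs and ``tip_depths`` gives each taxon's
    root-to-tip path length. Tips of the tree not among ``taxa`` carry no
    counts and never contribute (the tree is effectively pruned: traversal
    is rooted at the lowest common ancestor of the retained taxa); ``taxa``
    missing from the tree are an error.
    """
    tip_names = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in tip_names]
    if missing:
        raise TreeError(f"taxa absent from the OTU tree: {', '.join(map(str, missing[:5]))}")
    index = {t: i for i, t in enumerate(taxa)}
    below: dict[int, list[int]] = {}
    eff_root = tree
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            below[id(node)] = [index[node.name]] if node.name in index else []
        else:
            below[id(node)] = [i for ch in node.children for i in below[id(ch)]]
        if len(below[id(node)]) == len(taxa) and eff_root is tree:
            eff_root = node  # postorder: the first full-coverage node is the LCA
    branches: list[tuple[float, list[int]]] = []
    depths = np.zeros(len(taxa))

    def walk(node: TreeNode, depth: float) -> None:
        for child in node.children:
            if not below[id(child)]:
                continue
            if child.length is None:
                raise TreeError("UniFrac requires branch lengths on every branch")
            d = depth + float(child.length)
            branches.append((float(child.length), below[id(child)]))
            if child.is_tip():
                depths[index[child.name]] = d
            else:
                walk(child, d)

    walk(eff_root, 0.0)
    return branches, depths


def _as_vector(x, taxa: list[str] | None):
    """Accept a mapping/Series keyed by taxon, or a vector aligned to ``taxa``."""
    if isinstance(x, dict):
        x = pd.Series(x, dtype=float)
    if isinstance(x, pd.Series):
        taxa_out = list(x.index) if taxa is None else taxa
        return x.reindex(taxa_out, fill_value=0.0).to_numpy(), taxa_out
    if taxa is None:
        raise ValueError("taxa must be given when counts are a plain vector")
    return np.asarray(x, dtype=float), list(taxa)


def unweighted_unifrac(x_presence, y_presence, otu_tree: TreeNode, taxa: list[str] | None = None) -> float:
    """Presence/absence UniFrac: unique branch length / observed branch length.

    ``x_presence``/``y_presence`` may be sets of taxon labels, or count
    vectors aligned to ``taxa`` (any positive count marks presence).
    """
    if isinstance(x_presence, (set, frozenset, list, tuple)) and taxa is None and all(
        isinstance(v, str) for v in x_presence
    ):
        taxa = sorted(set(x_presence) | set(y_presence))
        xv = np.array([1 if t in set(x_presence) else 0 for t in taxa], dtype=float)
        yv = np.array([1 if t in set(y_presence) else 0 for t in taxa], dtype=float)
    else:
        xv, taxa = _as_vector(x_presence, taxa)
        yv, _ = _as_vector(y_presence, taxa)
    branches, _ = _tree_branches(otu_tree, taxa)
    return _unweighted(branches, xv > 0, yv > 0)


def _unweighted(branches, x_present: np.ndarray, y_present: np.ndarray) -> float:
    if not x_present.any() and not y_present.any():
        raise ValueError("UniFrac is undefined when both samples are empty")
    unique = observed = 0.0
    for length, tips in branches:
        if not tips:
            continue
        in_x = any(x_present[i] for i in tips)
        in_y = any(y_present[i] for i in tips)
        if in_x or in_y:
            observed += length
            if in_x != in_y:
                unique += length
    return unique / observed if observed else 0.0


def weighted_unifrac(x, y, otu_tree: TreeNode, normalized: bool = True, taxa: list[str] | None = None) -> float:
    """Abundance-weighted UniFrac.

    The normalized variant (default) divides by the maximal value attainable
    given the tree and the two samples' tip proportions, bounding the result
    to [0, 1]; the raw variant is the plain branch-length-weighted sum of
    proportion differences.
    """
    xv, taxa = _as_vector(x, taxa)
    yv, _ = _as_vector(y, taxa)
    branches, depths = _tree_branches(otu_tree, taxa)
    return _weighted(branches, xv, yv, depths if normalized else None)


def _weighted(branches, x: np.ndarray, y: np.ndarray, tip_depths: np.ndarray | None) -> float:
    if x.sum() == 0 or y.sum() == 0:
        raise ValueError("weighted UniFrac needs nonzero totals in both samples")
    px, py = x / x.sum(), y / y.sum()
    d = 0.0
    for length, tips in branches:
        if not tips:
            continue
        d += length * abs(sum(px[i] for i in tips) - sum(py[i] for i in tips))
    if tip_depths is None:
        return d
    denom = float((tip_depths * (px + py)).sum())
    return d / denom if denom else 0.0


_METRICS = ("braycurtis", "unifrac", "wunifrac")


def pairwise_distances(
    table: OtuTable,
    metric: str = "braycurtis",
    otu_tree: TreeNode | None = None,
    normalized: bool = True,
) -> DistanceMatrix:
    """Apply ``metric`` to every pair of samples (columns) of ``table``.

    ``metric`` is one of ``braycurtis``, ``unifrac`` (unweighted) or
    ``wunifrac`` (weighted; ``normalized`` selects the bounded variant).
    UniFrac metrics require ``otu_tree``.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose one of {_METRICS}")
    ids = table.sample_ids
    X = table.counts.to_numpy(dtype=float).T  # samples x otus
    if metric == "braycurtis":
        if X.shape[0] == 1:
            data = np.zeros((1, 1))
        else:
            data = squareform(pdist(X, metric="braycurtis"))
        return DistanceMatrix(data, ids=ids)
    if otu_tree is None:
        raise ValueError("UniFrac metrics require an OTU tree")
    taxa = table.otu_ids
    branches, all_depths = _tree_branches(otu_tree, taxa)
    depths = all_depths if (metric == "wunifrac" and normalized) else None
    n = len(ids)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "unifrac":
                d = _unweighted(branches, X[i] > 0, X[j] > 0)
            else:
                d = _weighted(branches, X[i], X[j], depths)
            data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids=ids)


@dataclass
class PcoaResult:
    """Principal coordinates of a distance matrix.

    ``coordinates`` has one row per label and one column per axis (axes
    ordered by descending eigenvalue; only positive-eigenvalue axes carry
    coordinates). ``negative_axes`` flags eigenvalues below zero, which
    arise for non-Euclidean dissimilarities and are reported uncorrected.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_axes: np.ndarray


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical metric multidimensional scaling of ``dm``."""
    if isinstance(dm, DistanceMatrix):
        D = dm.data
        ids = list(dm.ids)
    else:
        D = np.asarray(dm, dtype=float)
        if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
            raise ValueError("distance matrix must be square and symmetric")
        ids = [str(i) for i in range(D.shape[0])]
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    pos = eigvals > 0
    coords = np.zeros((n, n))
    coords[:, pos] = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    proportion = np.where(pos, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    columns = [f"PC{i + 1}" for i in range(n)]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=columns),
        eigenvalues=eigvals,
        proportion_explained=proportion,
        negative_axes=eigvals < 0,
    )
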