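"""Statistical stages of the phylosymbiosis analysis and the orchestrated run.

The individual stages are usable on their own: jackknifed species
dendrograms, ANOSIM, the intraspecific-vs-interspecific distance test, the
clade-age regression, the per-taxon Kruskal-Wallis screen and the transplant
OTU-overlap summary. :func:`run_full` wires them together from a single
configuration mapping.

A deliberate caveat inherited from the underlying design: the Mann-Whitney
comparison of intraspecific vs interspecific distances treats the pairwise
distances as independent observations, which they are not (each sample
appears in many pairs). The test is reported as-is; its p-values should be
read as descriptive.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.stats as st
from skbio import DistanceMatrix, TreeNode
from statsmodels.stats.multitest import multipletests

from . import beta as _beta
from . import io as _io
from . import prep as _prep
from . import trees as _trees
from .errors import PipelineError, TreeError
from .io import OtuTable, SampleMetadata

__all__ = [
    "AnosimResult",
    "MannWhitneyResult",
    "RegressionResult",
    "ScreenRecord",
    "TransferSummary",
    "anosim",
    "intra_inter_test",
    "clade_age_regression",
    "kw_screen",
    "donor_transfer_summary",
    "jackknifed_dendrogram",
    "run_full",
]


# ---------------------------------------------------------------------------
# Result types
# ---------------------------------------------------------------------------


@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MannWhitneyResult:
    u: float
    p_value: float
    n_intra: int
    n_inter: int
    intra_summary: dict[str, float]
    inter_summary: dict[str, float]
    method: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    log_transform: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ScreenRecord:
    taxon: str
    group_means: dict[str, float]
    p_value: float
    p_fdr: float
    p_bonferroni: float
    testable: bool = True


@dataclass
class TransferSummary:
    donor: str
    pct_shared_otus: float
    pct_donor_specific_transferred: float | None
    pct_recipient_abundance: float
    n_donor_specific: int

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------


def anosim(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> AnosimResult:
    """Analysis of similarities (Clarke's R) with a permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M / 2), where
    M = n(n-1)/2 pairwise distances are ranked together (midranks for ties).
    Significance: group labels are permuted across samples and
    p = #(permuted R >= observed R) / n_permutations.
    """
    groups = list(groups)
    if len(groups) != len(dm.ids):
        raise ValueError("one group label per distance-matrix id is required")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    small = [str(l) for l, c in zip(labels, counts) if c < 2]
    if small:
        raise ValueError(f"every group needs >= 2 members; too small: {', '.join(small)}")
    n = len(dm.ids)
    iu, ju = np.triu_indices(n, k=1)
    ranks = st.rankdata(dm.data[iu, ju])
    m = len(ranks)
    g = np.asarray(pd.factorize(np.asarray(groups))[0])

    def r_stat(gvec: np.ndarray) -> float:
        within = gvec[iu] == gvec[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    observed = r_stat(g)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(g)) >= observed:
            count += 1
    return AnosimResult(
        r=float(observed),
        p_value=count / n_permutations,
        n_permutations=n_permutations,
        group_sizes={str(l): int(c) for l, c in zip(labels, counts)},
    )


# ---------------------------------------------------------------------------
# Intra vs inter distances
# ---------------------------------------------------------------------------

EXACT_MWU_MAX = 8  # exact null enumeration up to this smaller-group size


def _summary(values: np.ndarray) -> dict[str, float]:
    if len(values) == 0:
        return {"median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    return {
        "median": float(np.median(values)),
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
    }


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U: exact null when the smaller group has <= 8
    observations and there are no ties, normal approximation with tie
    correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= EXACT_MWU_MAX and not has_ties) else "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(
        u=float(res.statistic),
        p_value=float(res.pvalue),
        n_intra=len(x),
        n_inter=len(y),
        intra_summary=_summary(x),
        inter_summary=_summary(y),
        method=method,
    )


def intra_inter_test(
    dm: DistanceMatrix, metadata: SampleMetadata
) -> tuple[MannWhitneyResult, dict[tuple[str, str], np.ndarray]]:
    """Compare intraspecific vs interspecific pairwise distances.

    Partitions the n(n-1)/2 distances by whether the two samples share a
    host species, runs a two-sided Mann-Whitney U on the two sets, and also
    returns every species-pair distance group (keys are sorted species
    pairs; a pair of identical species holds the intraspecific distances of
    that species).
    """
    species = [metadata.species_of(s) for s in dm.ids]
    n = len(dm.ids)
    intra, inter = [], []
    pair_groups: dict[tuple[str, str], list[float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = dm.data[i, j]
            key = tuple(sorted((species[i], species[j])))
            pair_groups.setdefault(key, []).append(float(d))
            (intra if species[i] == species[j] else inter).append(float(d))
    if not intra or not inter:
        raise ValueError("need both intraspecific and interspecific sample pairs")
    result = mann_whitney(np.array(intra), np.array(inter))
    return result, {k: np.asarray(v) for k, v in pair_groups.items()}


# ---------------------------------------------------------------------------
# Clade-age regression
# ---------------------------------------------------------------------------


def clade_age_regression(points, log_transform: bool = True) -> RegressionResult:
    """OLS of ANOSIM R on (log10-transformed) clade divergence age.

    ``points`` is an iterable of (age_in_mya, anosim_r) pairs; significance
    is the two-sided t-test on the slope.
    """
    pts = [(float(a), float(r)) for a, r in points]
    if len(pts) < 3:
        raise ValueError("regression needs at least 3 points (no residual df below 3)")
    ages = np.array([a for a, _ in pts])
    rs = np.array([r for _, r in pts])
    if log_transform:
        if np.any(ages <= 0):
            raise ValueError("log-transformed regression requires strictly positive ages")
        ages = np.log10(ages)
    fit = st.linregress(ages, rs)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(pts),
        log_transform=log_transform,
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis taxon screen
# ---------------------------------------------------------------------------


def kw_screen(table: OtuTable, groups) -> list[ScreenRecord]:
    """Per-taxon Kruskal-Wallis across host groups with FDR and Bonferroni
    corrections over all taxa in the table.

    ``table`` is normally a taxonomy-collapsed relative-abundance table;
    ``groups`` assigns one group label per sample (column). Taxa constant
    across all samples are untestable and given p = 1. Records are returned
    sorted by ascending raw p-value.
    """
    groups = np.asarray(list(groups))
    if len(groups) != table.n_samples:
        raise ValueError("one group label per sample is required")
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    raw_p = []
    records = []
    for taxon in table.otu_ids:
        row = table.counts.loc[taxon].to_numpy(dtype=float)
        parts = [row[groups == g] for g in labels]
        means = {str(g): float(p.mean()) for g, p in zip(labels, parts)}
        if np.allclose(row, row[0]):
            records.append(ScreenRecord(taxon, means, 1.0, 1.0, 1.0, testable=False))
            raw_p.append(1.0)
            continue
        stat, p = st.kruskal(*parts)
        records.append(ScreenRecord(taxon, means, float(p), np.nan, np.nan))
        raw_p.append(float(p))
    raw_p = np.asarray(raw_p)
    _, p_fdr, _, _ = multipletests(raw_p, method="fdr_bh")
    p_bonf = np.minimum(raw_p * len(raw_p), 1.0)
    for rec, f, b in zip(records, p_fdr, p_bonf):
        rec.p_fdr = float(f)
        rec.p_bonferroni = float(b)
    records.sort(key=lambda r: (r.p_value, r.taxon))
    return records


# ---------------------------------------------------------------------------
# Transplant OTU-overlap summary
# ---------------------------------------------------------------------------


def donor_transfer_summary(
    donor_table: OtuTable,
    recipient_post_table: OtuTable,
    recipient_control_table: OtuTable,
    donor: str = "donor",
) -> TransferSummary:
    """Summarize how much of a donor community appears in transplant recipients.

    Donor-specific OTUs are those present in the donor community but absent
    from untreated control recipients. The summary reports the percentage of
    donor OTUs shared with post-transplant recipients, the percentage of
    donor-specific OTUs that transferred, and the share of post-transplant
    sequence abundance carried by donor-specific OTUs. When the donor has no
    specific OTUs the transfer percentage is undefined (None).
    """

    def present(table: OtuTable) -> set[str]:
        sums = table.counts.sum(axis=1)
        return set(sums.index[sums > 0])

    donor_otus = present(donor_table)
    control_otus = present(recipient_control_table)
    post_otus = present(recipient_post_table)
    if not donor_otus:
        raise ValueError("donor table has no observed OTUs")
    shared = donor_otus & post_otus
    donor_specific = donor_otus - control_otus
    transferred = donor_specific & post_otus
    if donor_specific:
        pct_transferred = 100.0 * len(transferred) / len(donor_specific)
    else:
        warnings.warn("no donor-specific OTUs (donor community is a subset of controls)")
        pct_transferred = None
    post_total = float(recipient_post_table.counts.to_numpy().sum())
    in_specific = float(
        recipient_post_table.counts.loc[sorted(transferred)].to_numpy().sum()
    ) if transferred else 0.0
    return TransferSummary(
        donor=donor,
        pct_shared_otus=100.0 * len(shared) / len(donor_otus),
        pct_donor_specific_transferred=pct_transferred,
        pct_recipient_abundance=100.0 * in_specific / post_total if post_total else 0.0,
        n_donor_specific=len(donor_specific),
    )


# ---------------------------------------------------------------------------
# Jackknifed dendrogram
# ---------------------------------------------------------------------------


def jackknifed_dendrogram(
    species_table: OtuTable,
    n_rarefactions: int = 1000,
    depth: int | None = None,
    metric: str = "braycurtis",
    otu_tree: TreeNode | None = None,
    seed: int | np.random.Generator | None = None,
) -> TreeNode:
    """Master microbiota dendrogram with jackknife support values.

    Rarefies the species-collapsed table ``n_rarefactions`` times to
    ``depth`` (default: the smallest species column sum), computes the
    chosen beta-diversity distance for each replicate, UPGMA-clusters the
    element-wise mean distance matrix into the master dendrogram, and
    annotates each internal node with the fraction of per-replicate UPGMA
    trees containing its cluster (stored on ``node.support``).
    """
    if species_table.n_samples < 3:
        raise ValueError("need at least 3 species to build a dendrogram")
    if n_rarefactions < 1:
        raise ValueError("n_rarefactions must be >= 1")
    sums = species_table.sample_sums
    if depth is None:
        depth = int(sums.min())
    if depth > sums.min():
        raise ValueError(f"depth {depth} exceeds the smallest species count sum {int(sums.min())}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_data = None
    replicate_clusters: list[frozenset[frozenset[str]]] = []
    ids = species_table.sample_ids
    for _ in range(n_rarefactions):
        rare = _prep.rarefy(species_table, depth, rng)
        dm = _beta.pairwise_distances(rare, metric, otu_tree=otu_tree)
        mean_data = dm.data if mean_data is None else mean_data + dm.data
        replicate_clusters.append(_trees.extract_clusters(_trees.upgma(dm)))
    mean_dm = DistanceMatrix(mean_data / n_rarefactions, ids=ids)
    master = _trees.upgma(mean_dm)
    n = len(ids)
    for node in master.non_tips(include_self=True):
        cluster = frozenset(t.name for t in node.tips())
        if 2 <= len(cluster) < n:
            node.support = sum(cluster in rc for rc in replicate_clusters) / n_rarefactions
        else:
            node.support = None
    return master


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "metric": "braycurtis",
    "exclude": ["chloroplast", "unassigned", "wolbachia"],
    "rarefy_depth": "auto",
    "n_rarefactions": 100,
    "n_random_trees": 100_000,
    "n_permutations": 1000,
    "seed": 42,
    "kw_rank": "class",
}


def run_full(config: dict, output_dir: str | None = None) -> dict:
    """Execute the whole analysis from a configuration mapping.

    Recognized keys: ``table``, ``metadata``, ``clade_ages`` (file paths or
    in-memory objects), ``host_trees`` (mapping clade -> Newick path or
    tree), ``otu_tree``, plus the tuning knobs in ``_DEFAULTS``. Stages:
    taxon filtering and rarefaction; per clade the intra/inter distance
    test, ANOSIM over species, the jackknifed dendrogram, and (when a host
    tree is available) the RF and MC congruence tests; across clades the
    clade-age regression and the Kruskal-Wallis taxon screen. Any stage
    failure aborts with the stage name; outputs written so far are kept.

    Returns a JSON-serializable results bundle; when ``output_dir`` is given
    the bundle and per-stage tables/trees are also written there.
    """
    cfg = {**_DEFAULTS, **config}
    seed = int(cfg["seed"])
    out: dict = {"parameters": {k: v for k, v in cfg.items() if isinstance(v, (int, float, str, list))}}
    if output_dir:
        os.makedirs(output_dir, exist_ok=True)
        os.makedirs(os.path.join(output_dir, "distances"), exist_ok=True)
        os.makedirs(os.path.join(output_dir, "dendrograms"), exist_ok=True)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # --- load inputs -----------------------------------------------------
    ld = stage("load")
    table = cfg["table"]
    if not isinstance(table, OtuTable):
        table = ld(_io.read_otu_table, table)
    metadata = cfg["metadata"]
    if not isinstance(metadata, SampleMetadata):
        metadata = ld(_io.read_metadata, metadata, cfg.get("clade_ages"))
    host_trees: dict[str, TreeNode] = {}
    for clade, tree in (cfg.get("host_trees") or {}).items():
        host_trees[clade] = tree if isinstance(tree, TreeNode) else ld(_io.read_newick, tree)
    otu_tree = cfg.get("otu_tree")
    if otu_tree is not None and not isinstance(otu_tree, TreeNode):
        otu_tree = ld(_io.read_newick, otu_tree)

    # --- prep ------------------------------------------------------------
    pr = stage("prep")
    table = pr(_prep.filter_taxa, table, cfg["exclude"]) if table.taxonomy else table
    depth_cfg = cfg["rarefy_depth"]
    if depth_cfg not in (None, "none"):
        depth = int(table.sample_sums.min()) if depth_cfg == "auto" else int(depth_cfg)
        table = pr(_prep.rarefy, table, depth, seed)
        out["rarefaction_depth"] = depth
    out["alpha_diversity"] = pr(_prep.alpha_diversity, table).to_dict(orient="records")

    # --- per clade -------------------------------------------------------
    metric = cfg["metric"]
    clades = metadata.clades()
    out["clades"] = {}
    anosim_by_clade: dict[str, float] = {}
    for c_idx, clade in enumerate(clades):
        samples = [s for s in table.sample_ids if metadata.clade_of(s) == clade]
        clade_table = OtuTable(table.counts[samples], dict(table.taxonomy) if table.taxonomy else None)
        clade_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(c_idx,)).generate_state(1)[0] % (2**31))
        result: dict = {}
        bd = stage(f"beta[{clade}]")
        dm = bd(_beta.pairwise_distances, clade_table, metric, otu_tree)
        if output_dir:
            _io.write_distance_matrix(dm, os.path.join(output_dir, "distances", f"{clade}_{metric}.tsv"))
        ii = stage(f"intra_inter[{clade}]")
        try:
            mwu, _groups = ii(intra_inter_test, dm, metadata)
            result["intra_inter"] = mwu.to_dict()
        except PipelineError as exc:
            warnings.warn(str(exc))
        an = stage(f"anosim[{clade}]")
        groups = [metadata.species_of(s) for s in dm.ids]
        if len(set(groups)) >= 2 and min(np.unique(groups, return_counts=True)[1]) >= 2:
            res = an(anosim, dm, groups, int(cfg["n_permutations"]), clade_seed)
            result["anosim"] = res.to_dict()
            anosim_by_clade[clade] = res.r
        dd = stage(f"dendrogram[{clade}]")
        species_table = dd(_prep.collapse_by_species, clade_table, metadata)
        if species_table.n_samples >= 3:
            dendro = dd(
                jackknifed_dendrogram,
                species_table,
                int(cfg["n_rarefactions"]),
                None,
                metric,
                otu_tree,
                clade_seed,
            )
            if output_dir:
                for node in dendro.non_tips(include_self=True):
                    if getattr(node, "support", None) is not None:
                        node.name = f"{node.support:.3f}"
                _io.write_newick(dendro, os.path.join(output_dir, "dendrograms", f"{clade}.nwk"))
                for node in dendro.non_tips(include_self=True):
                    node.name = None
            if clade in host_trees:
                cg = stage(f"congruence[{clade}]")
                result["congruence"] = {}
                for m in ("rf", "mc"):
                    res = cg(
                        _trees.congruence_test,
                        host_trees[clade],
                        dendro,
                        m,
                        int(cfg["n_random_trees"]),
                        clade_seed,
                    )
                    result["congruence"][m] = res.to_dict()
            else:
                warnings.warn(f"no host tree for clade {clade!r}; congruence stage skipped")
        out["clades"][clade] = result

    # --- cross clade -----------------------------------------------------
    if metadata.clade_age and len(anosim_by_clade) >= 3:
        usable = [
            (metadata.clade_age[c], r)
            for c, r in anosim_by_clade.items()
            if c in metadata.clade_age
        ]
        if len(usable) >= 3:
            rg = stage("age_regression")
            out["age_regression"] = rg(clade_age_regression, usable, True).to_dict()
    if table.taxonomy and len(clades) >= 2:
        kw = stage("kw_screen")
        collapsed = kw(_prep.collapse_taxonomy, table, cfg["kw_rank"])
        relabund = _prep.relative_abundance(collapsed)
        sample_clades = [metadata.clade_of(s) for s in relabund.sample_ids]
        records = kw(kw_screen, relabund, sample_clades)
        out["kw_screen"] = [
            {
                "taxon": r.taxon,
                "p_value": r.p_value,
                "p_fdr": r.p_fdr,
                "p_bonferroni": r.p_bonferroni,
                "testable": r.testable,
            }
            for r in records
        ]
        if output_dir:
            pd.DataFrame(out["kw_screen"]).to_csv(
                os.path.join(output_dir, "screen.tsv"), sep="\t", index=False
            )

    if output_dir:
        with open(os.path.join(output_dir, "results.json"), "w", encoding="utf-8") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
    return out
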