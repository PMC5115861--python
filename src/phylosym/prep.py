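"""Community table preprocessing: taxon filtering, rarefaction, taxonomy and
species collapsing, and alpha diversity.

These are the quality-control and aggregation stages applied to an OTU count
table before beta-diversity and congruence analyses. Filtering removes
lineages that are sequencing artifacts or known confounders (chloroplast
reads, unassigned sequences, intracellular endosymbionts such as
*Wolbachia*); rarefaction subsamples every sample without replacement to a
common depth so that richness and dissimilarity are comparable across
samples.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import FormatError
from .io import OtuTable, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "filter_taxa",
    "rarefy",
    "collapse_taxonomy",
    "relative_abundance",
    "collapse_by_species",
    "shannon",
    "chao1",
    "alpha_diversity",
    "RANKS",
]

#: Supported taxonomic ranks, shallowest first. Collapsing below genus is not
#: supported (species-level 16S assignments are unreliable at these read
#: lengths, and the lineage strings rarely carry them).
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


def filter_taxa(table: OtuTable, exclude_patterns: list[str]) -> OtuTable:
    """Remove OTUs whose lineage matches any of ``exclude_patterns``.

    Matching is case-insensitive substring search over the lineage string.
    OTUs with no taxonomy at all are treated as matching the pattern
    ``"unassigned"`` so that an unassigned-filter removes them too.
    """
    if not exclude_patterns:
        raise ValueError("exclude_patterns must be non-empty")
    patterns = [p.lower() for p in exclude_patterns]
    taxonomy = table.taxonomy or {}
    removed_per_pattern = {p: 0 for p in patterns}
    keep = []
    for otu in table.otu_ids:
        lineage = taxonomy.get(otu)
        haystack = lineage.lower() if lineage else "unassigned"
        matched = False
        for p in patterns:
            if p in haystack:
                removed_per_pattern[p] += 1
                matched = True
        if not matched:
            keep.append(otu)
    for p, n in removed_per_pattern.items():
        logger.info("filter_taxa: pattern %r removed %d OTUs", p, n)
    if not keep:
        warnings.warn("filter_taxa removed every OTU; returning an empty table")
    counts = table.counts.loc[keep]
    new_tax = {o: taxonomy[o] for o in keep if o in taxonomy} or None
    return OtuTable(counts, new_tax)


def rarefy(
    table: OtuTable,
    depth: int,
    seed: int | np.random.Generator | None = None,
    drop_below: bool = False,
) -> OtuTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Each sample's counts are drawn from a multivariate hypergeometric
    distribution (sampling reads without replacement), so every retained
    column sums exactly to ``depth``. Samples shallower than ``depth`` are an
    error unless ``drop_below=True``, in which case they are dropped with a
    warning.
    """
    if depth < 0:
        raise ValueError("rarefaction depth must be nonnegative")
    sums = table.sample_sums
    values = table.counts.to_numpy()
    if values.size and not np.allclose(values, np.round(values)):
        raise FormatError("rarefaction requires integer counts")
    shallow = [s for s in table.sample_ids if sums[s] < depth]
    if shallow and not drop_below:
        raise ValueError(
            f"depth {depth} exceeds the count sum of samples: {', '.join(shallow)}"
        )
    if shallow:
        warnings.warn(f"rarefy dropped {len(shallow)} samples shallower than depth {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keep = [s for s in table.sample_ids if s not in set(shallow)]
    out = pd.DataFrame(0.0, index=table.otu_ids, columns=keep)
    for s in keep:
        col = np.round(table.counts[s].to_numpy()).astype(np.int64)
        out[s] = rng.multivariate_hypergeometric(col, depth)
    tax = dict(table.taxonomy) if table.taxonomy else None
    return OtuTable(out, tax)


def collapse_taxonomy(table: OtuTable, rank: str) -> OtuTable:
    """Sum OTU rows by lineage prefix truncated at ``rank``.

    OTUs whose lineage does not reach ``rank`` (or that have no taxonomy)
    pool into a single ``unclassified-at-<rank>`` row. Column sums are
    conserved exactly.
    """
    rank = rank.lower()
    if rank not in RANKS:
        raise ValueError(f"unsupported rank {rank!r}; choose one of {RANKS}")
    if table.taxonomy is None:
        raise FormatError("collapse_taxonomy requires taxonomy annotations")
    level = RANKS.index(rank)
    unclassified = f"unclassified-at-{rank}"
    groups: dict[str, list[str]] = {}
    for otu in table.otu_ids:
        lineage = table.taxonomy.get(otu)
        if lineage is None:
            key = unclassified
        else:
            fields = [f.strip() for f in lineage.split(";")]
            key = "; ".join(fields[: level + 1]) if len(fields) > level else unclassified
        groups.setdefault(key, []).append(otu)
    rows = {key: table.counts.loc[otus].sum(axis=0) for key, otus in groups.items()}
    counts = pd.DataFrame(rows).T
    counts = counts.loc[sorted(counts.index)]
    counts.columns = table.sample_ids
    return OtuTable(counts, None)


def relative_abundance(table: OtuTable) -> OtuTable:
    """Normalize each sample (column) to sum to 1. All-zero columns are left
    untouched with a warning."""
    sums = table.sample_sums
    zero_cols = [s for s in table.sample_ids if sums[s] == 0]
    if zero_cols:
        warnings.warn(f"relative_abundance: all-zero samples left unchanged: {zero_cols}")
    safe = sums.replace(0, 1.0)
    counts = table.counts / safe
    tax = dict(table.taxonomy) if table.taxonomy else None
    return OtuTable(counts, tax)


def collapse_by_species(table: OtuTable, metadata: SampleMetadata) -> OtuTable:
    """Sum counts across all samples of each host species, producing one
    column per species (the "representative species microbiota profile")."""
    for s in table.sample_ids:
        if s not in metadata.sample_species:
            raise FormatError(f"sample {s!r} absent from metadata")
    species_order: dict[str, list[str]] = {}
    for s in table.sample_ids:
        species_order.setdefault(metadata.species_of(s), []).append(s)
    counts = pd.DataFrame(
        {sp: table.counts[samples].sum(axis=1) for sp, samples in species_order.items()}
    )
    tax = dict(table.taxonomy) if table.taxonomy else None
    return OtuTable(counts, tax)


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log(p_i), in bits by default."""
    x = np.asarray(counts, dtype=float)
    if x.sum() <= 0:
        raise ValueError("Shannon diversity is undefined for an all-zero vector")
    p = x[x > 0] / x.sum()
    return float(-(p * (np.log(p) / np.log(base))).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1)).

    F1 and F2 are the singleton and doubleton counts; the bias-corrected
    form is defined even when no doubletons are observed.
    """
    x = np.round(np.asarray(counts, dtype=float)).astype(np.int64)
    if np.any(np.asarray(counts, dtype=float) < 0):
        raise ValueError("counts must be nonnegative")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(table: OtuTable, metrics: tuple[str, ...] = ("shannon", "chao1")) -> pd.DataFrame:
    """Per-sample alpha diversity as a long-form (sample, metric, value) table."""
    funcs = {"shannon": shannon, "chao1": chao1}
    records = []
    for metric in metrics:
        if metric not in funcs:
            raise ValueError(f"unknown alpha diversity metric {metric!r}")
        for s in table.sample_ids:
            records.append((s, metric, funcs[metric](table.counts[s].to_numpy())))
    return pd.DataFrame(records, columns=["sample", "metric", "value"])
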