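"""Readers and writers for the pipeline's external representations.

Supported formats
-----------------
* OTU tables: classic tab-delimited (OTU rows x sample columns, optional
  trailing ``taxonomy`` column) and the BIOM 1.0 JSON dialect (sparse or
  dense).
* Trees: Newick, through scikit-bio's parser, with strict leaf-label
  validation on top.
* Sample metadata: tab-delimited ``sample / species / clade`` tables with an
  optional companion table of clade divergence ages.
* Distance matrices: tab-delimited square matrices with a label header.

All readers validate their input and raise :class:`~phylosym.errors.FormatError`
naming the offending record; all writers are the exact inverse of the
corresponding reader (round-trip identity) and are bit-stable given identical
inputs.
"""

from __future__ import annotations

import io as _io
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .errors import FormatError, TreeError

__all__ = [
    "OtuTable",
    "SampleMetadata",
    "read_otu_table",
    "write_otu_table",
    "read_newick",
    "write_newick",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
]

_TAXONOMY_HEADERS = {"taxonomy", "consensus lineage", "consensuslineage"}


def _check_no_tabs(label: str, what: str) -> None:
    if "\t" in str(label):
        raise FormatError(f"{what} {label!r} contains an embedded tab; tabs are not quotable in this dialect")


@dataclass
class OtuTable:
    """A counts matrix of OTUs (rows) by samples (columns).

    Parameters
    ----------
    counts : pandas.DataFrame
        Nonnegative counts (or relative abundances) indexed by OTU id, with
        one column per sample id.
    taxonomy : dict, optional
        Mapping from OTU id to a ranked, semicolon-delimited lineage string
        (GreenGenes-style ``k__...; p__...; ...; g__...``). Keys must be a
        subset of the OTU ids.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)
        dup_otus = self.counts.index[self.counts.index.duplicated()]
        if len(dup_otus):
            raise FormatError(f"duplicate OTU id {dup_otus[0]!r}")
        dup_samples = self.counts.columns[self.counts.columns.duplicated()]
        if len(dup_samples):
            raise FormatError(f"duplicate sample id {dup_samples[0]!r}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("counts must be numeric")
        if values.size and np.nanmin(values) < 0:
            otu_i, samp_i = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at OTU {self.counts.index[otu_i]!r}, "
                f"sample {self.counts.columns[samp_i]!r}"
            )
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.counts.index)
            if unknown:
                raise FormatError(f"taxonomy refers to unknown OTU id {sorted(unknown)[0]!r}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_sums(self) -> pd.Series:
        """Sequencing depth per sample (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def lineage(self, otu_id: str) -> str | None:
        if self.taxonomy is None:
            return None
        return self.taxonomy.get(otu_id)

    def copy(self) -> "OtuTable":
        return OtuTable(self.counts.copy(), dict(self.taxonomy) if self.taxonomy else None)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        same_tax = (self.taxonomy or {}) == (other.taxonomy or {})
        return (
            same_tax
            and self.counts.shape == other.counts.shape
            and list(self.counts.index) == list(other.counts.index)
            and list(self.counts.columns) == list(other.counts.columns)
            and np.allclose(self.counts.to_numpy(dtype=float), other.counts.to_numpy(dtype=float))
        )


@dataclass
class SampleMetadata:
    """Maps samples to host species, species to host clades, and (optionally)
    clades to divergence ages in millions of years."""

    sample_species: dict[str, str]
    species_clade: dict[str, str]
    clade_age: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for sample, species in self.sample_species.items():
            if species not in self.species_clade:
                raise FormatError(f"sample {sample!r} has species {species!r} with no clade assignment")
        if self.clade_age is not None:
            for clade, age in self.clade_age.items():
                if not (age > 0):
                    raise FormatError(f"clade {clade!r} has non-positive divergence age {age!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_species)

    def species_of(self, sample: str) -> str:
        try:
            return self.sample_species[sample]
        except KeyError:
            raise FormatError(f"sample {sample!r} absent from metadata") from None

    def clade_of(self, sample: str) -> str:
        return self.species_clade[self.species_of(sample)]

    def species_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for sp in self.sample_species.values():
            seen.setdefault(sp)
        return list(seen)

    def samples_of_species(self, species: str) -> list[str]:
        return [s for s, sp in self.sample_species.items() if sp == species]

    def clades(self) -> list[str]:
        seen: dict[str, None] = {}
        for clade in self.species_clade.values():
            seen.setdefault(clade)
        return list(seen)

    def species_in_clade(self, clade: str) -> list[str]:
        return [sp for sp, cl in self.species_clade.items() if cl == clade]


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------


def _sniff_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "biom-json"):
            raise FormatError(f"unknown OTU table format {fmt!r}; expected 'tsv' or 'biom-json'")
        return fmt
    ext = os.path.splitext(str(path))[1].lower()
    return "biom-json" if ext in (".biom", ".json") else "tsv"


def read_otu_table(path: str, format: str | None = None) -> OtuTable:
    """Read an OTU table from ``path``.

    ``format`` may be ``'tsv'`` (classic QIIME tab-delimited, OTU rows by
    sample columns with a header row and an optional trailing taxonomy
    column) or ``'biom-json'``; when omitted it is sniffed from the file
    extension (``.biom``/``.json`` mean BIOM, everything else TSV).
    """
    fmt = _sniff_format(path, format)
    if fmt == "biom-json":
        with open(path, encoding="utf-8") as fh:
            return _parse_biom_json(json.load(fh))
    with open(path, encoding="utf-8") as fh:
        return _parse_tsv(fh.read())


def _parse_tsv(text: str) -> OtuTable:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    # Classic tables may carry a leading "# Constructed from ..." comment;
    # the header is the last leading '#' line (or the first line if none).
    header_idx = 0
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            header_idx = i
        else:
            break
    if not lines:
        raise FormatError("empty OTU table file")
    header = lines[header_idx].lstrip("#").split("\t")
    if len(header) < 1:
        raise FormatError("OTU table header row is empty")
    sample_ids = header[1:]
    has_taxonomy = bool(sample_ids) and sample_ids[-1].strip().lower() in _TAXONOMY_HEADERS
    if has_taxonomy:
        sample_ids = sample_ids[:-1]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise FormatError(f"duplicate sample id {sid!r} in header")
        seen.add(sid)
    otu_ids: list[str] = []
    rows: list[list[float]] = []
    taxonomy: dict[str, str] = {}
    n_fields = 1 + len(sample_ids) + (1 if has_taxonomy else 0)
    for ln in lines[header_idx + 1 :]:
        fields = ln.split("\t")
        if len(fields) != n_fields:
            raise FormatError(
                f"row {fields[0]!r} has {len(fields)} fields, expected {n_fields}"
            )
        otu = fields[0]
        if otu in set(otu_ids):
            raise FormatError(f"duplicate OTU id {otu!r}")
        values = fields[1 : 1 + len(sample_ids)]
        row = []
        for sid, v in zip(sample_ids, values):
            try:
                row.append(float(v))
            except ValueError:
                raise FormatError(
                    f"non-numeric count {v!r} at OTU {otu!r}, sample {sid!r}"
                ) from None
            if row[-1] < 0:
                raise FormatError(f"negative count at OTU {otu!r}, sample {sid!r}")
        otu_ids.append(otu)
        rows.append(row)
        if has_taxonomy and fields[-1].strip():
            taxonomy[otu] = fields[-1].strip()
    counts = pd.DataFrame(rows, index=otu_ids, columns=sample_ids, dtype=float)
    return OtuTable(counts, taxonomy or None)


def write_otu_table(table: OtuTable, path: str, format: str | None = None) -> None:
    """Write ``table`` to ``path`` as the exact inverse of :func:`read_otu_table`."""
    fmt = _sniff_format(path, format)
    for sid in table.sample_ids:
        _check_no_tabs(sid, "sample id")
    for oid in table.otu_ids:
        _check_no_tabs(oid, "OTU id")
    if fmt == "biom-json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_to_biom_json(table), fh, sort_keys=True)
            fh.write("\n")
        return
    has_taxonomy = table.taxonomy is not None
    with open(path, "w", encoding="utf-8") as fh:
        header = ["#OTU ID", *table.sample_ids]
        if has_taxonomy:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for otu in table.otu_ids:
            row = [otu] + [_format_count(v) for v in table.counts.loc[otu]]
            if has_taxonomy:
                lineage = table.taxonomy.get(otu, "")
                _check_no_tabs(lineage, "taxonomy lineage")
                row.append(lineage)
            fh.write("\t".join(row) + "\n")


def _format_count(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _parse_biom_json(doc: dict) -> OtuTable:
    try:
        shape = doc["shape"]
        rows = doc["rows"]
        cols = doc["columns"]
        data = doc["data"]
        matrix_type = doc.get("matrix_type", "sparse")
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed BIOM JSON: missing key {exc}") from None
    otu_ids = [str(r["id"]) for r in rows]
    sample_ids = [str(c["id"]) for c in cols]
    counts = np.zeros((int(shape[0]), int(shape[1])), dtype=float)
    if matrix_type == "dense":
        for i, row in enumerate(data):
            counts[i, :] = row
    elif matrix_type == "sparse":
        for i, j, v in data:
            counts[int(i), int(j)] = v
    else:
        raise FormatError(f"unsupported BIOM matrix_type {matrix_type!r}")
    taxonomy: dict[str, str] = {}
    for r in rows:
        meta = r.get("metadata") or {}
        tax = meta.get("taxonomy")
        if tax:
            taxonomy[str(r["id"])] = "; ".join(tax) if isinstance(tax, list) else str(tax)
    return OtuTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids), taxonomy or None)


def _to_biom_json(table: OtuTable) -> dict:
    values = table.counts.to_numpy(dtype=float)
    data = [
        [i, j, values[i, j]]
        for i in range(values.shape[0])
        for j in range(values.shape[1])
        if values[i, j] != 0
    ]
    rows = []
    for otu in table.otu_ids:
        lineage = (table.taxonomy or {}).get(otu)
        meta = {"taxonomy": [f.strip() for f in lineage.split(";")]} if lineage else None
        rows.append({"id": otu, "metadata": meta})
    return {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "phylosym",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": list(values.shape),
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_newick(path_or_string: str, midpoint_root: bool = False) -> TreeNode:
    """Parse a rooted tree from a Newick file path or literal string.

    Leaf labels are validated for uniqueness and branch lengths for
    nonnegativity. ``midpoint_root=True`` re-roots the tree at its midpoint
    (the convention used for OTU trees built from marker-gene alignments).
    """
    text = path_or_string
    if "(" not in text and ";" not in text:
        # no Newick syntax characters: must be a path
        with open(path_or_string, encoding="utf-8") as fh:
            text = fh.read()
    try:
        tree = TreeNode.read(_io.StringIO(text), format="newick")
    except Exception as exc:  # scikit-bio raises its own parse errors
        raise FormatError(f"Newick parse error: {exc}") from None
    names = [tip.name for tip in tree.tips()]
    if any(n is None or n == "" for n in names):
        raise TreeError("tree has an unnamed leaf")
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise TreeError(f"duplicate leaf label {n!r}")
        seen.add(n)
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise TreeError(f"negative branch length on node {node.name!r}")
    if midpoint_root:
        tree = tree.root_at_midpoint()
    return tree


def write_newick(tree: TreeNode, path: str) -> None:
    """Write ``tree`` in Newick format (inverse of :func:`read_newick`)."""
    tree.write(path, format="newick")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------


def read_metadata(path: str, clade_table: str | None = None) -> SampleMetadata:
    """Read a ``sample / species / clade`` tab-delimited table.

    ``clade_table`` optionally points to a companion two-column table
    (``clade``, ``age_mya``) of clade divergence ages; when absent, ages are
    unavailable and operations that need them (the clade-age regression)
    refuse to run.
    """
    sample_species: dict[str, str] = {}
    species_clade: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError("empty metadata file")
    header = [h.strip().lower().lstrip("#") for h in lines[0].split("\t")]
    try:
        s_i, sp_i, cl_i = header.index("sample"), header.index("species"), header.index("clade")
    except ValueError:
        raise FormatError("metadata header must contain 'sample', 'species' and 'clade' columns") from None
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) < len(header):
            raise FormatError(f"metadata row {fields[0]!r} has too few fields")
        sample, species, clade = fields[s_i], fields[sp_i], fields[cl_i]
        if sample in sample_species:
            if sample_species[sample] != species:
                raise FormatError(
                    f"sample {sample!r} listed twice with conflicting species "
                    f"({sample_species[sample]!r} vs {species!r})"
                )
            continue
        if species in species_clade and species_clade[species] != clade:
            raise FormatError(
                f"species {species!r} assigned to two clades "
                f"({species_clade[species]!r} and {clade!r})"
            )
        sample_species[sample] = species
        species_clade[species] = clade
    clade_age = None
    if clade_table is not None:
        clade_age = {}
        with open(clade_table, encoding="utf-8") as fh:
            rows = [ln.rstrip("\n") for ln in fh if ln.strip()]
        for ln in rows[1:]:  # header: clade <tab> age_mya
            clade, age = ln.split("\t")[:2]
            try:
                clade_age[clade] = float(age)
            except ValueError:
                raise FormatError(f"non-numeric age {age!r} for clade {clade!r}") from None
    return SampleMetadata(sample_species, species_clade, clade_age)


def write_metadata(metadata: SampleMetadata, path: str, clade_table: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tspecies\tclade\n")
        for sample, species in metadata.sample_species.items():
            fh.write(f"{sample}\t{species}\t{metadata.species_clade[species]}\n")
    if clade_table is not None and metadata.clade_age is not None:
        with open(clade_table, "w", encoding="utf-8") as fh:
            fh.write("clade\tage_mya\n")
            for clade, age in metadata.clade_age.items():
                fh.write(f"{clade}\t{age!r}\n")


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

_SYMMETRY_TOL = 1e-9


def read_distance_matrix(path: str) -> DistanceMatrix:
    """Read a tab-delimited square distance matrix with a label header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("distance matrix row labels do not match column labels")
    values = df.to_numpy(dtype=float)
    asym = np.abs(values - values.T)
    if asym.size and asym.max() > _SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise FormatError(
            f"asymmetry beyond tolerance between {df.index[i]!r} and {df.index[j]!r}: "
            f"{values[i, j]!r} vs {values[j, i]!r}"
        )
    diag = np.abs(np.diag(values))
    if diag.size and diag.max() > _SYMMETRY_TOL:
        i = int(np.argmax(diag))
        raise FormatError(f"nonzero diagonal entry for {df.index[i]!r}")
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, ids=list(df.index))


def write_distance_matrix(dm: DistanceMatrix, path: str) -> None:
    for label in dm.ids:
        _check_no_tabs(label, "distance matrix label")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(dm.ids) + "\n")
        for i, label in enumerate(dm.ids):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in dm.data[i]) + "\n")
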