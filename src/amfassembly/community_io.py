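"""Readers, writers and validation for the pipeline's shared domain types.

The pipeline's universal currency is the :class:`OtuTable` (samples x OTUs
count matrix), accompanied by a rooted phylogeny over the OTU tips (a
:class:`dendropy.Tree`) and per-sample metadata (habitat category, distance
to the urban center, soil properties and heavy-metal concentrations).

Orientation of OTU tables on disk is never guessed: the caller states whether
samples are rows or columns.  Silent transposition is the classic OTU-table
bug, and a 60 x 300 table transposed parses just fine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("amfassembly")

#: The four urbanization categories used throughout.
CATEGORIES = ("urban", "suburban", "exurban", "rural")

#: Soil variables carried in metadata (soil organic matter, available
#: phosphorus, soil moisture content, available potassium, pH, total nitrogen).
SOIL_VARS = ("SOM", "AP", "SMC", "AK", "pH", "TN")

#: The five heavy metals whose concentrations (mg/kg) feed the pollution index.
METALS = ("Cd", "Zn", "Fe", "Cu", "Pb")


class FormatError(ValueError):
    """A file violated its format contract (duplicate ids, bad cell, ...)."""


class ConfigError(ValueError):
    """A configuration value is out of its admissible range."""


# ---------------------------------------------------------------------------
# OtuTable
# ---------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Samples x OTUs non-negative count matrix with id labels.

    Invariants enforced at construction: unique sample and OTU ids, all
    counts finite and >= 0, matching shapes.  Empty rows/columns are *not*
    rejected here; :meth:`drop_empty` (called by the readers) removes them
    with a logged warning.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_otus), float64

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        n_s, n_o = self.counts.shape
        if n_s != len(self.sample_ids) or n_o != len(self.otu_ids):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != n_s:
            raise FormatError("duplicate sample ids")
        if len(set(self.otu_ids)) != n_o:
            raise FormatError("duplicate OTU ids")
        if not np.all(np.isfinite(self.counts)):
            raise FormatError("non-finite count value")
        if np.any(self.counts < 0):
            raise FormatError("negative count value")

    # -- shape helpers ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundances(self) -> np.ndarray:
        """Row-normalised counts; rows must have positive totals."""
        totals = self.sample_totals()
        if np.any(totals <= 0):
            raise ValueError("cannot normalise a sample with zero total count")
        return self.counts / totals[:, None]

    # -- filtering ----------------------------------------------------------
    def drop_empty(self) -> "OtuTable":
        """Drop all-zero samples and OTUs, logging what was removed."""
        keep_s = self.counts.sum(axis=1) > 0
        keep_o = self.counts.sum(axis=0) > 0
        if not keep_s.all():
            dropped = [s for s, k in zip(self.sample_ids, keep_s) if not k]
            logger.warning("dropping %d all-zero sample(s): %s", len(dropped), dropped)
        if not keep_o.all():
            dropped = [o for o, k in zip(self.otu_ids, keep_o) if not k]
            logger.warning("dropping %d all-zero OTU(s): %s", len(dropped), dropped)
        if keep_s.all() and keep_o.all():
            return self
        return OtuTable(
            [s for s, k in zip(self.sample_ids, keep_s) if k],
            [o for o, k in zip(self.otu_ids, keep_o) if k],
            self.counts[np.ix_(keep_s, keep_o)],
        )

    def subset_otus(self, otu_ids: list[str]) -> "OtuTable":
        """Column subset in the given order; unknown ids raise KeyError."""
        index = {o: i for i, o in enumerate(self.otu_ids)}
        try:
            cols = [index[o] for o in otu_ids]
        except KeyError as exc:
            raise KeyError(f"unknown OTU id {exc.args[0]!r}") from None
        return OtuTable(list(self.sample_ids), list(otu_ids), self.counts[:, cols])

    def subset_samples(self, sample_ids: list[str]) -> "OtuTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids), self.counts[rows, :])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


def read_otu_table(
    path,
    orientation: str = "samples_as_rows",
    drop_empty: bool = True,
) -> OtuTable:
    """Read a tab-separated OTU table into a validated :class:`OtuTable`.

    ``orientation`` must be ``samples_as_rows`` or ``otus_as_rows``; it is
    never auto-detected.  Lines starting with ``#`` are treated as comments
    (provenance headers written by the simulator).
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    with open(path) as fh:
        header = next(
            (line for line in fh if line.strip() and not line.startswith("#")), ""
        )
    cols = header.rstrip("\n").split("\t")[1:]
    if len(set(cols)) != len(cols):  # pandas would silently mangle these
        raise FormatError(f"duplicate ids in OTU table header of {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        raise FormatError(f"duplicate ids in OTU table {path}")
    if orientation == "otus_as_rows":
        df = df.T
    try:
        counts = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in OTU table {path}: {exc}") from None
    table = OtuTable(list(df.index), list(df.columns), counts)
    return table.drop_empty() if drop_empty else table


def write_otu_table(table: OtuTable, path, header: str | None = None) -> None:
    """Write a table as TSV (samples as rows); ``header`` becomes a # comment."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df = table.to_dataframe()
        # integer tables round-trip bit-exactly
        if np.all(df.to_numpy() == np.round(df.to_numpy())):
            df = df.astype(int)
        df.to_csv(fh, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

def read_tree(path, missing_lengths: str = "error") -> dendropy.Tree:
    """Parse a rooted newick tree with branch lengths.

    ``missing_lengths`` is ``"error"`` (reject trees with absent edge
    lengths) or ``"zero"`` (treat them as 0, the root edge excepted).
    """
    if missing_lengths not in ("error", "zero"):
        raise ConfigError(f"missing_lengths must be 'error' or 'zero', got {missing_lengths!r}")
    from pathlib import Path
    if not Path(path).exists():
        raise FileNotFoundError(
            f"tree file not found: {path} (a phylogeny is required for the βNTI stage)"
        )
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises assorted error types
        raise FormatError(f"unparseable newick in {path}: {exc}") from None
    return _validate_tree(tree, missing_lengths)


def tree_from_string(newick: str, missing_lengths: str = "error") -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    except Exception as exc:
        raise FormatError(f"unparseable newick: {exc}") from None
    return _validate_tree(tree, missing_lengths)


def _validate_tree(tree: dendropy.Tree, missing_lengths: str) -> dendropy.Tree:
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lbl is None for lbl in labels):
        raise FormatError("tree has unlabeled tips")
    if len(set(labels)) != len(labels):
        raise FormatError("tip label collision in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue  # root edge length is irrelevant to patristic distances
        if edge.length is None:
            if missing_lengths == "error":
                raise FormatError("tree edge with missing branch length")
            edge.length = 0.0
        elif edge.length < 0:
            raise FormatError("negative branch length")
    return tree


def prune_tree(tree: dendropy.Tree, otu_ids: list[str]) -> dendropy.Tree:
    """Return a copy of ``tree`` pruned to the requested tip set."""
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = set(otu_ids) - tips
    if missing:
        raise ValueError(f"{len(missing)} OTU id(s) absent from tree, e.g. {sorted(missing)[:3]}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(list(otu_ids))
    return pruned


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMetadata:
    """One sampling site: habitat category, distance, soil and metals."""

    sample_id: str
    category: str
    distance_km: float
    soil: dict[str, float] = field(default_factory=dict)
    metals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r} for sample {self.sample_id}; "
                f"expected one of {CATEGORIES}"
            )
        if self.distance_km < 0:
            raise ValueError(f"negative distance for sample {self.sample_id}")


def read_metadata(path, require_metals: bool = True) -> list[SampleMetadata]:
    """Read per-sample metadata CSV into validated records.

    Requires ``sample_id``, ``category`` and ``distance_km`` columns.  When
    ``require_metals`` is true (the default, needed whenever pollution
    indices will be computed) all five metal columns must be present.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("sample_id", "category", "distance_km"):
        if col not in df.columns:
            raise FormatError(f"metadata {path} missing required column {col!r}")
    if require_metals:
        missing = [m for m in METALS if m not in df.columns]
        if missing:
            raise ValueError(f"metadata {path} missing metal column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        soil = {v: float(row[v]) for v in SOIL_VARS if v in df.columns}
        metals = {m: float(row[m]) for m in METALS if m in df.columns}
        records.append(
            SampleMetadata(str(row["sample_id"]), str(row["category"]),
                           float(row["distance_km"]), soil, metals)
        )
    if len({r.sample_id for r in records}) != len(records):
        raise FormatError(f"duplicate sample ids in metadata {path}")
    return records


def metadata_frame(records: list[SampleMetadata]) -> pd.DataFrame:
    """Flatten metadata records into a DataFrame indexed by sample_id."""
    rows = []
    for r in records:
        row = {"sample_id": r.sample_id, "category": r.category,
               "distance_km": r.distance_km}
        row.update(r.soil)
        row.update(r.metals)
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def write_metadata(records: list[SampleMetadata], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        metadata_frame(records).to_csv(fh, index_label="sample_id")


def read_backgrounds(path) -> dict[str, float]:
    """Read per-element background concentrations (CSV: element,background)."""
    df = pd.read_csv(path, comment="#")
    if "element" not in df.columns or "background" not in df.columns:
        raise FormatError(f"background file {path} needs 'element' and 'background' columns")
    bg = {str(r.element): float(r.background) for r in df.itertuples()}
    missing = [m for m in METALS if m not in bg]
    if missing:
        raise ValueError(f"background file {path} missing element(s): {missing}")
    return bg


def align(table: OtuTable, records: list[SampleMetadata]) -> tuple[OtuTable, list[SampleMetadata]]:
    """Join-safety: return table and metadata over the identical, identically
    ordered sample set (table order wins).  Samples present in only one of
    the two inputs raise a ValueError."""
    meta_ids = {r.sample_id for r in records}
    table_ids = set(table.sample_ids)
    if meta_ids != table_ids:
        only_t = sorted(table_ids - meta_ids)[:3]
        only_m = sorted(meta_ids - table_ids)[:3]
        raise ValueError(
            f"sample sets differ between table and metadata "
            f"(table-only e.g. {only_t}, metadata-only e.g. {only_m})"
        )
    by_id = {r.sample_id: r for r in records}
    return table, [by_id[s] for s in table.sample_ids]
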