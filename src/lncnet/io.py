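"""Readers and writers for every file the pipeline touches.

All tables are tab-separated UTF-8 with a mandatory header row and a plain
decimal point.  Readers validate aggressively and raise :class:`FormatError`
naming the offending row or column, so downstream modules can assume clean,
typed in-memory structures.

Formats handled here:

* expression matrix TSV (first column gene id, header row of sample ids)
* design TSV (``sample``, ``group``)
* annotation TSV (``gene_id``, ``symbol``, ``biotype``)
* GMT gene-set collections
* clinical follow-up TSV (``sample``, ``time``, ``event``, ``expression``,
  plus arbitrary binary covariate columns)
* scored interaction TSVs
* SIF network export with node/edge attribute sidecars
* YAML run configuration
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Mapping
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_annotation",
    "read_design",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_interactions",
    "write_interactions",
    "write_network_sif",
    "load_config",
]

BIOTYPES = ("lncRNA", "mRNA")
GENESET_CATEGORIES = ("BP", "CC", "MF", "KEGG")


class FormatError(ValueError):
    """A file failed validation; the message names the offending element."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2 intensities with group design.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id, on the
        log2 scale.  All cells must be finite.
    design
        Series mapping every sample id to its group label (two groups for a
        case/control comparison, e.g. ``"case"``/``"control"``).
    biotype
        Series mapping every gene id to ``"lncRNA"`` or ``"mRNA"``.
    symbols
        Optional gene id -> display symbol mapping.
    """

    values: pd.DataFrame
    design: pd.Series
    biotype: pd.Series
    symbols: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        vals = self.values.to_numpy()
        if vals.size and not np.isfinite(vals.astype(float)).all():
            bad = np.argwhere(~np.isfinite(vals.astype(float)))[0]
            raise FormatError(
                f"non-finite value at gene {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise FormatError(f"sample {missing[0]!r} has no group label")
        self.design = self.design.reindex(self.values.columns)
        missing_bt = [g for g in self.values.index if g not in self.biotype.index]
        if missing_bt:
            raise FormatError(f"gene {missing_bt[0]!r} has no biotype annotation")
        self.biotype = self.biotype.reindex(self.values.index)
        bad_bt = set(self.biotype.unique()) - set(BIOTYPES)
        if bad_bt:
            raise FormatError(f"unknown biotype {sorted(bad_bt)[0]!r}")
        if self.symbols is not None:
            self.symbols = self.symbols.reindex(self.values.index)

    # -- convenience accessors ------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        return sorted(self.design.unique())

    def samples_in(self, group: str) -> list[str]:
        """Sample ids belonging to *group*."""
        sel = [s for s in self.values.columns if self.design[s] == group]
        if not sel:
            raise FormatError(f"no samples in group {group!r}")
        return sel

    def genes_of(self, biotype: str) -> list[str]:
        """Gene ids annotated with *biotype* (``"lncRNA"`` or ``"mRNA"``)."""
        return [g for g in self.values.index if self.biotype[g] == biotype]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.design.equals(other.design)
            and self.biotype.equals(other.biotype)
        )


def read_design(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise FormatError(f"design file missing column {col!r}")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise FormatError(f"duplicate sample id in design: {dup!r}")
    return df.set_index("sample")["group"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "symbol", "biotype"):
        if col not in df.columns:
            raise FormatError(f"annotation file missing column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene id in annotation: {dup!r}")
    return df.set_index("gene_id")


def read_expression(
    path: str | Path,
    design_path: str | Path,
    annotation_path: str | Path,
) -> ExpressionMatrix:
    """Read an expression TSV plus design and annotation sidecars."""
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.shape[1] < 2:
        raise FormatError("expression file needs a gene-id column and >=1 sample")
    gene_col = raw.columns[0]
    if raw[gene_col].duplicated().any():
        dup = raw.loc[raw[gene_col].duplicated(), gene_col].iloc[0]
        raise FormatError(f"duplicate gene id: {dup!r}")
    raw = raw.set_index(gene_col)
    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(f"non-numeric cell at gene {gene!r}, sample {col!r}")
        numeric[col] = converted
    design = read_design(design_path)
    ann = read_annotation(annotation_path)
    return ExpressionMatrix(
        values=numeric,
        design=design,
        biotype=ann["biotype"],
        symbols=ann["symbol"],
    )


def write_expression(
    matrix: ExpressionMatrix,
    path: str | Path,
    design_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if design_path is not None:
        d = matrix.design.rename("group")
        d.index.name = "sample"
        d.to_csv(design_path, sep="\t")
    if annotation_path is not None:
        symbols = (
            matrix.symbols
            if matrix.symbols is not None
            else pd.Series(matrix.gene_ids, index=matrix.gene_ids)
        )
        ann = pd.DataFrame({"symbol": symbols, "biotype": matrix.biotype})
        ann.index.name = "gene_id"
        ann.to_csv(annotation_path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    category: str  # one of GENESET_CATEGORIES
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in GENESET_CATEGORIES:
            raise FormatError(f"unknown gene-set category {self.category!r}")
        if not self.genes:
            raise FormatError(f"gene set {self.term_id!r} has no members")


class GeneSetCollection(Mapping[str, GeneSet]):
    """An ordered, id-unique collection of gene sets (GO terms, pathways)."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.term_id in self._sets:
                raise FormatError(f"duplicate term id {gs.term_id!r}")
            self._sets[gs.term_id] = gs

    def __getitem__(self, term_id: str) -> GeneSet:
        return self._sets[term_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def by_category(self, category: str) -> "GeneSetCollection":
        return GeneSetCollection(
            gs for gs in self._sets.values() if gs.category == category
        )

    def member_union(self) -> frozenset[str]:
        out: set[str] = set()
        for gs in self._sets.values():
            out |= gs.genes
        return frozenset(out)


def read_gmt(path: str | Path, category: str = "BP") -> GeneSetCollection:
    """Parse a GMT file (term, description, member genes...).

    The description field written by :func:`write_gmt` is ``category|name``;
    when a file from elsewhere lacks that encoding, *category* is used for
    every term.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"malformed GMT line {lineno}: expected >=3 fields")
            term_id, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"malformed GMT line {lineno}: term has no members")
            if "|" in desc and desc.split("|", 1)[0] in GENESET_CATEGORIES:
                cat, name = desc.split("|", 1)
            else:
                cat, name = category, desc or term_id
            sets.append(GeneSet(term_id, name, cat, frozenset(genes)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection.values():
            members = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.term_id}\t{gs.category}|{gs.name}\t{members}\n")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

CLINICAL_REQUIRED = ("sample", "time", "event", "expression")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical follow-up table; covariate columns pass through."""
    df = pd.read_csv(path, sep="\t")
    for col in CLINICAL_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"clinical file missing column {col!r}")
    if (df["time"] < 0).any():
        bad = df.loc[df["time"] < 0, "sample"].iloc[0]
        raise FormatError(f"negative survival time for sample {bad!r}")
    if not df["event"].isin([0, 1]).all():
        bad = df.loc[~df["event"].isin([0, 1]), "sample"].iloc[0]
        raise FormatError(f"event flag not in {{0,1}} for sample {bad!r}")
    return df


def write_clinical(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interaction tables
# ---------------------------------------------------------------------------


def read_interactions(
    path: str | Path, required_scores: Iterable[str] = ()
) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("interaction table needs source and target columns")
    for col in required_scores:
        if col not in df.columns:
            raise FormatError(f"interaction table missing score column {col!r}")
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"score column {col!r} is not numeric")
    return df


def write_interactions(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SIF network export
# ---------------------------------------------------------------------------


def write_network_sif(
    edges: pd.DataFrame,
    path_prefix: str | Path,
    source_col: str,
    target_col: str,
    interaction_col: str | None = None,
    node_attrs: pd.DataFrame | None = None,
    edge_attr_cols: Iterable[str] = (),
) -> Path:
    """Write a network as SIF plus node/edge attribute TSV sidecars.

    Produces ``<prefix>.sif`` (one line per edge: source, interaction type,
    target), ``<prefix>.edges.tsv`` with the requested edge attribute columns,
    and ``<prefix>.nodes.tsv`` when node attributes are supplied.  The files
    load directly into standard network viewers.

    Returns the path of the SIF file.
    """
    prefix = Path(path_prefix)
    sif_path = prefix.with_suffix(".sif")
    with open(sif_path, "w", encoding="utf-8") as fh:
        for _, row in edges.iterrows():
            itype = row[interaction_col] if interaction_col else "interacts"
            fh.write(f"{row[source_col]}\t{itype}\t{row[target_col]}\n")
    attr_cols = list(edge_attr_cols)
    keep = [source_col, target_col] + ([interaction_col] if interaction_col else [])
    edges[keep + [c for c in attr_cols if c not in keep]].to_csv(
        prefix.with_suffix(".edges.tsv"), sep="\t", index=False
    )
    if node_attrs is not None:
        out = node_attrs.copy()
        out.index.name = "node"
        out.to_csv(prefix.with_suffix(".nodes.tsv"), sep="\t")
    return sif_path


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError("run configuration must be a YAML mapping")
    return cfg
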