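"""lncRNA-mRNA coexpression network from Pearson correlation.

Edges connect a lncRNA and an mRNA whose log2 intensity profiles across all
samples (both groups pooled) correlate with |r| at or above a hard threshold
(default 0.99, inclusive).  With a 3-vs-3 design the near-unity correlations
that survive are driven by the shared group separation, which is exactly the
structure the screen exploits.  Degree centrality — the number of incident
edges — ranks nodes, and hub lncRNAs are those with degree >= 6.

The network is strictly bipartite by default; mRNA-mRNA edges can be added
with a flag for exploring strongly intercorrelated partner sets.  The sign of
r is retained as an edge attribute (positive/negative), matching the
solid/dotted display convention of network viewers.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Sequence
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as lio
from .io import ExpressionMatrix

__all__ = [
    "pearson_r",
    "CoexpressionNetwork",
    "build_network",
    "degree_centrality",
    "select_hubs",
]


def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("pearson_r requires length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        raise ValueError("undefined correlation: zero variance input")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


@dataclasses.dataclass
class CoexpressionNetwork:
    """Bipartite lncRNA-mRNA edge set with correlation attributes.

    ``edges`` has columns ``lncrna``, ``mrna``, ``r`` and ``sign``
    ("positive"/"negative").  ``lnc_ids``/``mrna_ids`` list all candidate
    nodes, so isolated genes report degree 0.  ``node_attrs`` optionally
    carries per-node metadata (biotype, regulation direction) for export.
    """

    edges: pd.DataFrame
    lnc_ids: tuple[str, ...]
    mrna_ids: tuple[str, ...]
    node_attrs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"lncrna", "mrna", "r", "sign"}
        missing = required - set(self.edges.columns)
        if missing:
            raise ValueError(f"edge table missing column {sorted(missing)[0]!r}")
        self.lnc_ids = tuple(self.lnc_ids)
        self.mrna_ids = tuple(self.mrna_ids)

    @classmethod
    def from_edge_list(
        cls,
        edges: pd.DataFrame,
        lnc_col: str = "lncrna",
        mrna_col: str = "mrna",
        r_col: str = "r",
        node_attrs: pd.DataFrame | None = None,
    ) -> "CoexpressionNetwork":
        """Wrap a plain (lncRNA, mRNA, r) edge table as a network."""
        df = edges[[lnc_col, mrna_col, r_col]].copy()
        df.columns = ["lncrna", "mrna", "r"]
        df["sign"] = np.where(df["r"] >= 0, "positive", "negative")
        return cls(
            edges=df,
            lnc_ids=tuple(dict.fromkeys(df["lncrna"])),
            mrna_ids=tuple(dict.fromkeys(df["mrna"])),
            node_attrs=node_attrs,
        )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> pd.Series:
        """Incident-edge count for every node (isolated nodes report 0)."""
        counts = pd.concat(
            [self.edges["lncrna"], self.edges["mrna"]]
        ).value_counts()
        nodes = list(self.lnc_ids) + [m for m in self.mrna_ids if m not in self.lnc_ids]
        return counts.reindex(nodes, fill_value=0).astype(int).rename("degree")

    def partners_of(self, node: str) -> list[str]:
        """Sorted coexpression partners of *node*."""
        out = set(self.edges.loc[self.edges["lncrna"] == node, "mrna"])
        out |= set(self.edges.loc[self.edges["mrna"] == node, "lncrna"])
        return sorted(out)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.lnc_ids, biotype="lncRNA")
        g.add_nodes_from(self.mrna_ids, biotype="mRNA")
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.lncrna, row.mrna, r=row.r, sign=row.sign)
        return g

    def write_sif(self, path_prefix: str | Path) -> Path:
        """Export via SIF with pos/neg interaction types and degree attrs."""
        attrs = pd.DataFrame({"degree": self.degree()})
        attrs["biotype"] = [
            "lncRNA" if n in set(self.lnc_ids) else "mRNA" for n in attrs.index
        ]
        if self.node_attrs is not None:
            attrs = attrs.join(self.node_attrs, how="left")
        sif = self.edges.copy()
        sif["interaction"] = np.where(sif["sign"] == "positive", "pos", "neg")
        return lio.write_network_sif(
            sif,
            path_prefix,
            source_col="lncrna",
            target_col="mrna",
            interaction_col="interaction",
            node_attrs=attrs,
            edge_attr_cols=("r", "sign"),
        )


def _standardize_rows(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale rows to unit norm; flags zero-variance rows."""
    centered = block - block.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    ok = norms > 0
    scaled = np.zeros_like(centered)
    scaled[ok] = centered[ok] / norms[ok, None]
    return scaled, ok


def build_network(
    matrix: ExpressionMatrix,
    lnc_ids: Sequence[str] | None = None,
    mrna_ids: Sequence[str] | None = None,
    r_threshold: float = 0.99,
    inclusive: bool = True,
    include_mrna_mrna: bool = False,
    node_attrs: pd.DataFrame | None = None,
) -> CoexpressionNetwork:
    """Threshold pairwise lncRNA-mRNA Pearson correlations into a network.

    Correlations are computed across all samples of both groups pooled.  An
    edge (l, m) is retained iff |r| >= r_threshold (strict > when
    ``inclusive=False``).  Genes with zero variance are skipped with a
    warning.  ``include_mrna_mrna=True`` additionally thresholds mRNA-mRNA
    pairs; those edges are stored with the lexicographically smaller id in
    the ``lncrna`` column.
    """
    if lnc_ids is None:
        lnc_ids = matrix.genes_of("lncRNA")
    if mrna_ids is None:
        mrna_ids = matrix.genes_of("mRNA")
    lnc_ids = [g for g in lnc_ids]
    mrna_ids = [g for g in mrna_ids]
    missing = [g for g in (*lnc_ids, *mrna_ids) if g not in matrix.values.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} not in expression matrix")
    if matrix.values.shape[1] < 3:
        raise ValueError("build_network requires >= 3 samples")

    X = matrix.values.loc[lnc_ids].to_numpy(dtype=float)
    Y = matrix.values.loc[mrna_ids].to_numpy(dtype=float)
    Xs, x_ok = _standardize_rows(X)
    Ys, y_ok = _standardize_rows(Y)
    skipped = [g for g, ok in zip(lnc_ids, x_ok) if not ok]
    skipped += [g for g, ok in zip(mrna_ids, y_ok) if not ok]
    if skipped:
        warnings.warn(
            f"skipping {len(skipped)} zero-variance gene(s), e.g. {skipped[0]!r}",
            stacklevel=2,
        )

    R = np.clip(Xs @ Ys.T, -1.0, 1.0)
    keep = np.abs(R) >= r_threshold if inclusive else np.abs(R) > r_threshold
    keep &= x_ok[:, None] & y_ok[None, :]
    li, mi = np.nonzero(keep)
    rows = pd.DataFrame(
        {
            "lncrna": np.asarray(lnc_ids, dtype=object)[li],
            "mrna": np.asarray(mrna_ids, dtype=object)[mi],
            "r": R[li, mi],
        }
    )

    if include_mrna_mrna:
        Rm = np.clip(Ys @ Ys.T, -1.0, 1.0)
        keep_m = np.abs(Rm) >= r_threshold if inclusive else np.abs(Rm) > r_threshold
        keep_m &= y_ok[:, None] & y_ok[None, :]
        iu, ju = np.nonzero(np.triu(keep_m, k=1))
        mm = pd.DataFrame(
            {
                "lncrna": np.asarray(mrna_ids, dtype=object)[iu],
                "mrna": np.asarray(mrna_ids, dtype=object)[ju],
                "r": Rm[iu, ju],
            }
        )
        rows = pd.concat([rows, mm], ignore_index=True)

    rows["sign"] = np.where(rows["r"] >= 0, "positive", "negative")
    rows = rows.sort_values(["lncrna", "mrna"], kind="mergesort").reset_index(drop=True)
    return CoexpressionNetwork(
        edges=rows,
        lnc_ids=tuple(lnc_ids),
        mrna_ids=tuple(mrna_ids),
        node_attrs=node_attrs,
    )


def degree_centrality(network: CoexpressionNetwork) -> pd.Series:
    """Integer incident-edge count per node, isolated nodes included as 0."""
    return network.degree()


def select_hubs(
    network: CoexpressionNetwork,
    min_degree: int = 6,
    restrict_to: str | None = "lncRNA",
) -> list[str]:
    """Nodes with degree >= min_degree, highest degree first, id as tiebreak.

    By default only lncRNA nodes are eligible (the hub-selection rule of the
    screen); pass ``restrict_to=None`` to rank all nodes.
    """
    deg = network.degree()
    if restrict_to == "lncRNA":
        deg = deg.loc[list(network.lnc_ids)]
    elif restrict_to == "mRNA":
        deg = deg.loc[[m for m in network.mrna_ids]]
    hubs = deg[deg >= min_degree]
    order = sorted(hubs.items(), key=lambda kv: (-kv[1], kv[0]))
    return [gene for gene, _ in order]
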