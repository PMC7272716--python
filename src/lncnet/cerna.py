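"""ceRNA (lncRNA-miRNA-mRNA) network assembly from scored interaction tables.

A cytoplasmic lncRNA can act as a competing endogenous RNA by sponging
miRNAs, relieving repression of the mRNAs those miRNAs target.  The network
is assembled purely by filtering user-supplied (or simulated) score tables —
no database is contacted:

* lncRNA-miRNA pairs survive when correlation score > 0.9 AND binding
  score > 0.04 (strict inequalities);
* miRNA-mRNA pairs survive when the cumulative weighted context++ score is
  <= -0.2 (inclusive; more negative = stronger predicted repression);
* a triplet (hub, miRNA, mRNA) is emitted when both links survive and, by
  default, the mRNA belongs to the hub's coexpression partner set.

Expected columns: ``lncrna``, ``mirna``, ``correlation_score``,
``binding_score`` for the first table; ``mirna``, ``mrna``,
``context_score`` for the second.
"""

from __future__ import annotations

from collections.abc import Iterable
from pathlib import Path

import pandas as pd

from . import io as lio

__all__ = ["filter_lnc_mirna", "filter_mirna_mrna", "assemble_cerna", "write_cerna_sif"]

LNC_MIRNA_COLS = ("lncrna", "mirna", "correlation_score", "binding_score")
MIRNA_MRNA_COLS = ("mirna", "mrna", "context_score")


def _require(table: pd.DataFrame, columns: Iterable[str]) -> None:
    for col in columns:
        if col not in table.columns:
            raise ValueError(f"interaction table missing column {col!r}")


def filter_lnc_mirna(
    table: pd.DataFrame, corr_min: float = 0.9, binding_min: float = 0.04
) -> pd.DataFrame:
    """Retain lncRNA-miRNA rows with correlation > corr_min and binding > binding_min."""
    _require(table, LNC_MIRNA_COLS)
    keep = (table["correlation_score"] > corr_min) & (
        table["binding_score"] > binding_min
    )
    return table[keep].reset_index(drop=True)


def filter_mirna_mrna(table: pd.DataFrame, context_max: float = -0.2) -> pd.DataFrame:
    """Retain miRNA-mRNA rows with context++ score <= context_max (inclusive)."""
    _require(table, MIRNA_MRNA_COLS)
    return table[table["context_score"] <= context_max].reset_index(drop=True)


def assemble_cerna(
    hub: str,
    lnc_mirna: pd.DataFrame,
    mirna_mrna: pd.DataFrame,
    hub_partners: Iterable[str] | None = None,
    corr_min: float = 0.9,
    binding_min: float = 0.04,
    context_max: float = -0.2,
    restrict_to_partners: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter both tables and chain them into hub-miRNA-mRNA triplets.

    Returns ``(triplets, summary)``: one row per surviving triplet with all
    three scores, deterministically sorted by (miRNA, mRNA), plus a summary
    with distinct miRNA / mRNA node counts and the triplet count.  With
    ``restrict_to_partners`` (the default) the mRNA side is intersected with
    the hub's coexpressed partner set, so the sponge network stays anchored
    to the coexpression evidence.
    """
    pairs1 = filter_lnc_mirna(lnc_mirna, corr_min=corr_min, binding_min=binding_min)
    pairs1 = pairs1[pairs1["lncrna"] == hub]
    pairs2 = filter_mirna_mrna(mirna_mrna, context_max=context_max)
    if restrict_to_partners:
        if hub_partners is None:
            raise ValueError("hub_partners required when restrict_to_partners=True")
        partner_set = set(hub_partners)
        pairs2 = pairs2[pairs2["mrna"].isin(partner_set)]

    triplets = pairs1.merge(pairs2, on="mirna", how="inner")
    triplets = triplets[
        ["lncrna", "mirna", "mrna", "correlation_score", "binding_score", "context_score"]
    ]
    triplets = triplets.sort_values(["mirna", "mrna"], kind="mergesort").reset_index(
        drop=True
    )
    summary = {
        "n_mirnas": int(triplets["mirna"].nunique()),
        "n_mrnas": int(triplets["mrna"].nunique()),
        "n_triplets": int(len(triplets)),
    }
    return triplets, summary


def write_cerna_sif(triplets: pd.DataFrame, path_prefix: str | Path) -> Path:
    """Export the ceRNA network as SIF (sponges / targets edge types)."""
    sponge = triplets[["lncrna", "mirna"]].drop_duplicates()
    sponge = sponge.rename(columns={"lncrna": "source", "mirna": "target"})
    sponge["interaction"] = "sponges"
    target = triplets[["mirna", "mrna"]].drop_duplicates()
    target = target.rename(columns={"mirna": "source", "mrna": "target"})
    target["interaction"] = "targets"
    edges = pd.concat([sponge, target], ignore_index=True)

    node_class = {}
    for n in triplets["lncrna"].unique():
        node_class[n] = "lncRNA"
    for n in triplets["mirna"].unique():
        node_class[n] = "miRNA"
    for n in triplets["mrna"].unique():
        node_class[n] = "mRNA"
    attrs = pd.DataFrame({"node_class": pd.Series(node_class, dtype=object)})
    return lio.write_network_sif(
        edges,
        path_prefix,
        source_col="source",
        target_col="target",
        interaction_col="interaction",
        node_attrs=attrs,
    )
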