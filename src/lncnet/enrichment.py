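"""Hypergeometric over-representation analysis and GO/KEGG overlap selection.

Given a study list of differentially expressed mRNAs and a gene-set
collection, each term is scored with the upper-tail hypergeometric test
P(X >= k) for the overlap k between study list and term, against a background
universe (by convention, all genes on the annotation table).  An EASE-style
conservative variant (testing k-1) is available via flag.

The selection step keeps the study mRNAs that belong to at least one
significant GO term AND at least one significant KEGG pathway — the
"overlapping in both analyses" rule used to narrow candidates before network
construction.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .diffexp import bh_fdr

__all__ = ["hypergeom_p", "enrich", "overlap_go_kegg"]


def hypergeom_p(k: int, K: int, n: int, N: int, ease: bool = False) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts study genes falling in a term of size *K* when *n* genes are
    drawn from a universe of *N*.  ``ease=True`` computes P(X >= k) with k
    reduced by one (never below zero), the conservative EASE variant.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if ease:
        k = max(k - 1, 0)
    # sf(k-1) == P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    study_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
    ease: bool = False,
) -> pd.DataFrame:
    """Score every term with overlap >= 1 against the study list.

    Returns a DataFrame with one row per overlapping term: ``term_id``,
    ``name``, ``category``, ``k``, ``K``, ``n``, ``N``, ``p``, ``fdr``,
    ``significant`` (raw p < alpha) and ``overlap_genes``, sorted by p then
    term id.  Terms are intersected with the universe before testing.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe must be non-empty")
    study = set(study_genes)
    outside = study - universe_set
    if outside:
        raise ValueError(f"study gene {sorted(outside)[0]!r} not in universe")
    n, N = len(study), len(universe_set)

    rows = []
    for gs in collection.values():
        members = gs.genes & universe_set
        overlap = sorted(study & members)
        k, K = len(overlap), len(members)
        if k == 0 or K == 0:
            continue
        rows.append(
            {
                "term_id": gs.term_id,
                "name": gs.name,
                "category": gs.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_p(k, K, n, N, ease=ease),
                "overlap_genes": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term_id", "name", "category", "k", "K", "n", "N",
                "p", "fdr", "significant", "overlap_genes",
            ]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["p"] < alpha
    out = out.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    return out[
        [
            "term_id", "name", "category", "k", "K", "n", "N",
            "p", "fdr", "significant", "overlap_genes",
        ]
    ]


def _genes_in_significant_terms(results: pd.DataFrame) -> set[str]:
    sig = results[results["significant"]]
    genes: set[str] = set()
    for cell in sig["overlap_genes"]:
        genes.update(g for g in str(cell).split(",") if g)
    return genes


def overlap_go_kegg(
    de_mrnas: Iterable[str],
    go_results: pd.DataFrame,
    kegg_results: pd.DataFrame,
) -> list[str]:
    """mRNAs that appear in >=1 significant GO term and >=1 significant pathway.

    The overlap is taken at the gene level: a study mRNA is retained exactly
    when it is a member of at least one significant term in each of the two
    analyses.  The result is sorted and duplicate-free, so the selection is
    idempotent and independent of input order.
    """
    go_genes = _genes_in_significant_terms(go_results)
    kegg_genes = _genes_in_significant_terms(kegg_results)
    return sorted(set(de_mrnas) & go_genes & kegg_genes)
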