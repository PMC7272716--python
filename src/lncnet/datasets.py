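"""Bundled worked-example tables from a published doxorubicin-resistance screen.

A breast-cancer microarray comparison of doxorubicin-resistant (MCF-7/ADR)
versus sensitive (MCF-7) cells reported six hub lncRNAs with their correlated
mRNA partners (fold change, p-value, regulation level, degree and Pearson r
per edge), the association of the top hub lnc-TRDMT1-5 with
clinicopathological features in a 20-patient validation cohort, and a ceRNA
network of five miRNAs and six mRNAs around that hub.  These small printed
tables are embedded here so the pipeline's network, statistics and assembly
stages can be exercised on real published values without any external data.

Gene symbols are normalised to standard HGNC spellings where the printed
table contains obvious transcription artefacts (e.g. MLC1, CALD1, S1PR1).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "hub_edge_table",
    "hub_gene_table",
    "clinicopathological_tables",
    "cerna_example_tables",
    "CERNA_HUB",
]

# (lncRNA id, alias, signed linear FC, p, level, [(mRNA, r), ...])
_HUBS = [
    (
        "ENST00000422749", "DSCAM-AS1:2", -281.293, 3.70e-05, "DOWN",
        [
            ("ZNF215", -0.99996), ("ZCCHC11", -0.99998), ("TP53I11", 0.999956),
            ("TMEM200A", -0.999985), ("TMEM106A", -0.999953), ("SRPX", -0.999975),
            ("RAB3B", -0.999951), ("NDN", -0.99998), ("MLC1", -0.999973),
            ("GRHL2", -0.99996), ("GPC5", -0.999953), ("GDA", -0.999962),
            ("CHRFAM7A", -0.999962), ("CALD1", -0.99997), ("CA12", -0.999957),
            ("BSPRY", -0.999956), ("ADRB2", -0.999954), ("ADAMTS6", -0.999972),
        ],
    ),
    (
        "NONHSAT057283", "lnc-MPPE1-13", 13.59, 0.00076, "UP",
        [
            ("ZCCHC11", 0.999978), ("TP53I11", -0.999961), ("TMEM200A", 0.999963),
            ("TMEM106A", 0.999986), ("SRPX", 0.999956), ("S1PR1", 0.99998),
            ("PSG8", 0.999971), ("NDN", 0.999989), ("MLC1", 0.999981),
            ("KRTAP2-3", 0.999948), ("GDA", 0.999959), ("CHRFAM7A", 0.999962),
            ("CD274", 0.999957), ("CALD1", 0.999954), ("BSPRY", -0.999964),
            ("BATF", -0.999951), ("ARHGAP40", 0.999979), ("ADRB2", 0.999951),
        ],
    ),
    (
        "ENST00000456355", "lnc-TRDMT1-5", 60.836, 0.00022, "UP",
        [
            ("TMEM200B", 0.999954), ("TBX18", 0.999978), ("ST6GALNAC3", 0.999984),
            ("SNURF", 0.999966), ("SNRPN", 0.999982), ("PRLR", -0.999955),
            ("NNMT", 0.999974), ("MSRB3", 0.99996), ("MSN", 0.99997),
            ("MCAM", 0.999991), ("LY6K", 0.999974), ("LAMC3", 0.999994),
            ("GSDMD", 0.999986), ("FOSL1", 0.999984),
        ],
    ),
    (
        "ENST00000455354", "DSCAM-AS1:5", -1394.049, 3.4e-05, "DOWN",
        [
            ("SLC7A2", 0.999956), ("S1PR1", -0.999981), ("OSBPL3", -0.999963),
            ("NDN", -0.999972), ("GPC5", -0.999974), ("CXCL12", 0.999957),
            ("CHRFAM7A", -0.999951), ("BSPRY", 0.999960),
        ],
    ),
    (
        "ENST00000594783", "ZNF667-AS1", 109.815, 0.00011, "UP",
        [
            ("THSD1", 0.999953), ("SAMD3", 0.999954), ("PSMB8", 0.999981),
            ("LAMC2", 0.999971), ("IGFBP3", 0.999962), ("ADRB2", 0.999951),
        ],
    ),
    (
        "NONHSAT097797", "lnc-CFI-3", -537.10388, 4.3e-05, "DOWN",
        [
            ("ZCCHC11", -0.999963), ("NDN", -0.999949), ("MLC1", -0.999965),
            ("CDH1", 0.999954), ("CA12", 0.999994), ("C5AR2", 0.999978),
            ("BSPRY", 0.999986),
        ],
    ),
]


def hub_edge_table() -> pd.DataFrame:
    """The published hub edge list: one row per lncRNA-mRNA edge (71 rows).

    Columns: ``lncrna``, ``alias``, ``fc``, ``p``, ``level``, ``mrna``, ``r``.
    """
    rows = []
    for lnc, alias, fc, p, level, partners in _HUBS:
        for mrna, r in partners:
            rows.append(
                {"lncrna": lnc, "alias": alias, "fc": fc, "p": p,
                 "level": level, "mrna": mrna, "r": r}
            )
    return pd.DataFrame(rows)


def hub_gene_table() -> pd.DataFrame:
    """Per-hub summary (fold change, p, level, published degree)."""
    return pd.DataFrame(
        [
            {"lncrna": lnc, "alias": alias, "fc": fc, "p": p, "level": level,
             "degree": len(partners)}
            for lnc, alias, fc, p, level, partners in _HUBS
        ]
    )


def clinicopathological_tables() -> dict[str, tuple[int, int, int, int]]:
    """Published 2x2 counts (a, b, c, d) per clinical feature, n = 20.

    Rows are the clinical categories, columns the expression groups
    (high, low): ``[[a, b], [c, d]]`` with a = category-1 & high expression.
    The lymph-node row is included for completeness although its published
    test statistic is not consistent with these counts under any standard
    chi-square variant.
    """
    return {
        "age": (9, 6, 2, 3),              # >45 vs <=45
        "lymph_node": (6, 2, 3, 9),       # metastasis yes vs no
        "er": (9, 3, 2, 6),               # positive vs negative
        "pr": (7, 3, 4, 6),               # positive vs negative
        "her2": (12, 2, 2, 4),            # positive vs negative
        "tnm": (5, 9, 5, 1),              # T1/T2 vs T3/T4
        "ki67": (2, 4, 11, 3),            # <=10% vs >10%
    }


CERNA_HUB = "ENST00000456355"

_CERNA_MIRNAS = ["miR-3173-5p", "miR-938", "miR-4704-3p", "miR-1265", "miR-644a"]

# invented miRNA -> target assignment covering the six published targets; the
# published figure reports only the node sets, not the individual edges
_CERNA_EDGES = [
    ("miR-3173-5p", "LY6K"), ("miR-3173-5p", "FOSL1"),
    ("miR-938", "GSDMD"),
    ("miR-4704-3p", "MSRB3"), ("miR-4704-3p", "MCAM"),
    ("miR-1265", "MCAM"), ("miR-1265", "ST6GALNAC3"),
    ("miR-644a", "FOSL1"), ("miR-644a", "LY6K"),
]


def cerna_example_tables() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scored interaction tables encoding the published ceRNA candidates.

    The candidate names (five miRNAs predicted to bind lnc-TRDMT1-5, six
    target mRNAs among its coexpression partners) are published; the
    numerical scores here are SYNTHETIC placeholders chosen to satisfy the
    published thresholds (correlation > 0.9, binding > 0.04, context++
    <= -0.2), and the individual miRNA->mRNA edges are an invented covering
    of the published node sets.  A few sub-threshold distractor rows are
    included so the filters do real work.
    """
    lnc_rows = [
        {"lncrna": CERNA_HUB, "mirna": m,
         "correlation_score": round(0.92 + 0.01 * i, 3),
         "binding_score": round(0.05 + 0.005 * i, 4)}
        for i, m in enumerate(_CERNA_MIRNAS)
    ]
    # distractors: one failing the correlation cutoff, one failing binding
    lnc_rows.append(
        {"lncrna": CERNA_HUB, "mirna": "miR-0000a",
         "correlation_score": 0.85, "binding_score": 0.06}
    )
    lnc_rows.append(
        {"lncrna": CERNA_HUB, "mirna": "miR-0000b",
         "correlation_score": 0.95, "binding_score": 0.03}
    )
    mirna_rows = [
        {"mirna": m, "mrna": t, "context_score": round(-0.25 - 0.02 * i, 3)}
        for i, (m, t) in enumerate(_CERNA_EDGES)
    ]
    # distractors: weak context score, and a target outside the partner set
    mirna_rows.append({"mirna": "miR-938", "mrna": "LY6K", "context_score": -0.1})
    mirna_rows.append({"mirna": "miR-938", "mrna": "ABCB1", "context_score": -0.5})
    return pd.DataFrame(lnc_rows), pd.DataFrame(mirna_rows)
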