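"""Two-group differential expression with a fold-change + p-value filter.

The comparison is the classic resistant-vs-sensitive microarray screen at
n = 3 per group: per-gene equal-variance Student's t-test on log2 intensities
plus a signed linear fold change, with a gene called UP/DOWN only when both
|FC| and p pass their thresholds (defaults |FC| >= 2, p < 0.05).  BH-adjusted
p-values are reported alongside but are not the primary filter.

Signed linear fold-change convention: ``log2FC = mean(case) - mean(control)``
and ``FC = 2**log2FC`` when that ratio is >= 1, else ``-2**(-log2FC)``, so a
gene halved in the case group carries FC = -2 and |FC| >= 1 always holds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = ["DERecord", "fold_change", "t_test", "bh_fdr", "call_de"]

UP, DOWN, NS = "UP", "DOWN", "NS"


@dataclasses.dataclass(frozen=True)
class DERecord:
    """Per-gene differential-expression result."""

    gene_id: str
    biotype: str
    fc: float  # signed linear fold change, |fc| >= 1
    log2fc: float
    t: float
    p: float
    fdr: float
    direction: str  # UP / DOWN / NS


def fold_change(case_values, control_values) -> tuple[float, float]:
    """Signed linear fold change and log2 fold change from log2 intensities.

    Returns ``(fc, log2fc)``.  ``log2fc`` is the difference of group means on
    the log2 scale; ``fc`` follows the signed convention above.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("fold_change requires non-empty groups")
    log2fc = float(case.mean() - control.mean())
    fc = float(2.0**log2fc) if log2fc >= 0 else float(-(2.0 ** (-log2fc)))
    return fc, log2fc


def t_test(case_values, control_values, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test on log2 intensities; returns ``(t, two-sided p)``.

    Equal-variance (Student's) by default, Welch via flag.  Zero pooled
    variance is handled by convention: equal means give p = 1, unequal means
    give p = 0 with an infinite statistic of the appropriate sign.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("t_test requires >= 2 replicates per group")
    if case.var(ddof=1) == 0.0 and control.var(ddof=1) == 0.0:
        diff = case.mean() - control.mean()
        if diff == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    res = stats.ttest_ind(case, control, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    matrix: ExpressionMatrix,
    case: str = "case",
    control: str = "control",
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Call differential expression for every gene in *matrix*.

    Returns a DataFrame indexed by gene id with columns ``biotype``, ``fc``,
    ``log2fc``, ``t``, ``p``, ``fdr`` and ``direction`` (UP when
    FC >= fc_threshold and p < p_threshold, DOWN when FC <= -fc_threshold and
    p < p_threshold, NS otherwise).
    """
    case_cols = matrix.samples_in(case)
    control_cols = matrix.samples_in(control)
    a = matrix.values[case_cols].to_numpy(dtype=float)
    b = matrix.values[control_cols].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("call_de requires >= 2 replicates per group")

    log2fc = a.mean(axis=1) - b.mean(axis=1)
    fc = np.where(log2fc >= 0, 2.0**log2fc, -(2.0 ** (-log2fc)))

    res = stats.ttest_ind(a, b, axis=1, equal_var=not welch)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # zero pooled variance -> scipy yields nan; apply the documented convention
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal = degenerate & (log2fc == 0.0)
        p[equal] = 1.0
        t[equal] = 0.0
        unequal = degenerate & (log2fc != 0.0)
        p[unequal] = 0.0
        t[unequal] = np.sign(log2fc[unequal]) * np.inf

    fdr = bh_fdr(p)
    direction = np.full(len(fc), NS, dtype=object)
    direction[(fc >= fc_threshold) & (p < p_threshold)] = UP
    direction[(fc <= -fc_threshold) & (p < p_threshold)] = DOWN

    return pd.DataFrame(
        {
            "biotype": matrix.biotype.to_numpy(),
            "fc": fc,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "direction": direction,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def de_summary(de_table: pd.DataFrame) -> pd.DataFrame:
    """Tally UP/DOWN/NS calls per biotype (lncRNA vs mRNA)."""
    return (
        de_table.groupby(["biotype", "direction"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=[UP, DOWN, NS], fill_value=0)
    )
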