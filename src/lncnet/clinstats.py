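"""Validation-side clinical statistics.

Covers the statistics used to relate a candidate transcript's expression to
clinicopathological features and tissue measurements: Pearson chi-square on
2x2 tables (no continuity correction by default — that choice reproduces the
printed associations of the worked example; Yates available via flag),
empirical ROC AUC via the rank-sum identity, relative qPCR quantification by
the 2^-ddCq method, and a paired t-test for tumor-vs-adjacent comparisons.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = [
    "Chi2Result",
    "chi_square_2x2",
    "roc_auc",
    "DdCqMeasurement",
    "ddcq",
    "paired_compare",
]


@dataclasses.dataclass(frozen=True)
class Chi2Result:
    chi2: float
    p: float
    df: int = 1


def chi_square_2x2(
    a: int, b: int, c: int, d: int, correction: bool = False
) -> Chi2Result:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]].

    Rows are the clinical category, columns the expression group.  Expected
    counts come from the margins; ``correction=True`` applies the Yates
    continuity correction.  Any zero margin makes the test undefined.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("counts must be non-negative integers")
    total = table.sum()
    if total <= 0:
        raise ValueError("empty table")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    expected = np.outer(row, col) / total
    dev = np.abs(table - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    return Chi2Result(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)))


def roc_auc(case_scores, control_scores) -> float:
    """Empirical AUC: P(case > control) + 0.5 P(tie), the rank-sum form."""
    case = np.asarray(case_scores, dtype=float)
    control = np.asarray(control_scores, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    u = stats.mannwhitneyu(case, control, alternative="two-sided").statistic
    return float(u / (case.size * control.size))


@dataclasses.dataclass(frozen=True)
class DdCqMeasurement:
    """Quantification-cycle readings for one relative-expression measurement.

    ``target``/``reference`` are the gene of interest and the housekeeping
    gene (e.g. GAPDH); ``sample``/``calibrator`` are the two conditions being
    compared (e.g. tumor vs adjacent tissue, resistant vs sensitive cells).
    """

    target_sample: float
    reference_sample: float
    target_calibrator: float
    reference_calibrator: float

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            v = getattr(self, field.name)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite Cq: {field.name}")


def ddcq(measurement: DdCqMeasurement) -> float:
    """Relative expression 2^-ddCq.

    dCq = Cq(target) - Cq(reference) within each condition;
    ddCq = dCq(sample) - dCq(calibrator).  A ddCq of -1 means one extra
    doubling in the sample, i.e. relative expression 2.0.
    """
    d_sample = measurement.target_sample - measurement.reference_sample
    d_cal = measurement.target_calibrator - measurement.reference_calibrator
    return float(2.0 ** (-(d_sample - d_cal)))


def paired_compare(tumor_values, adjacent_values) -> tuple[float, float]:
    """Paired Student's t-test on matched measurements; returns (t, p).

    Zero-variance differences follow the same convention as the two-sample
    test: identical pairs give t = 0, p = 1; a constant nonzero shift gives
    p = 0 with an infinite statistic of the shift's sign.
    """
    x = np.asarray(tumor_values, dtype=float)
    y = np.asarray(adjacent_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    if x.size < 2:
        raise ValueError("paired_compare requires n >= 2 pairs")
    diff = x - y
    if diff.var(ddof=1) == 0.0:
        if diff.mean() == 0.0:
            return 0.0, 1.0
        return float(np.sign(diff.mean()) * np.inf), 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
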