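"""Kaplan-Meier estimation, log-rank testing and O/E hazard ratios.

The analysis follows the standard high-vs-low expression stratification of a
follow-up cohort:

1. clean the cohort — drop records with expression exactly 0 and records with
   survival time under 30 days (both rules are reported separately; a record
   violating both is dropped once but counted under each);
2. split at the post-cleaning median expression (high = strictly above the
   median; alternative quantiles configurable);
3. product-limit (Kaplan-Meier) survival curves per group;
4. Mantel-Haenszel log-rank chi-square (1 df) with the hazard ratio estimated
   as (O_high/E_high)/(O_low/E_low), the classic observed-over-expected form.

Ties at an event time use the hypergeometric variance with d > 1.  A cohort
with no events at all reports chi2 = 0, p = 1 and an undefined (NaN) HR.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "clean_cohort",
    "split_by_expression",
    "km_curve",
    "logrank",
    "LogrankResult",
    "KMResult",
    "analyze_cohort",
    "subgroup_analysis",
]

MIN_FOLLOWUP_DAYS = 30.0


def clean_cohort(
    cohort: pd.DataFrame, min_time: float = MIN_FOLLOWUP_DAYS
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the cohort-cleaning filters; returns (filtered, drop report).

    Drops records whose expression value equals 0 and records whose survival
    time is below *min_time* days.  The report counts each rule separately
    (a record failing both is counted under both) plus the retained total.
    """
    zero = cohort["expression"] == 0
    short = cohort["time"] < min_time
    kept = cohort[~(zero | short)].copy()
    report = {
        "zero_expression": int(zero.sum()),
        "short_followup": int(short.sum()),
        "retained": int(len(kept)),
    }
    return kept, report


def split_by_expression(cohort: pd.DataFrame, quantile: float = 0.5) -> pd.Series:
    """Label each record "high" (> quantile cut) or "low" (<= cut).

    The cut point is computed on the cohort as given (i.e. after cleaning).
    With the default median and an odd number of distinct values the median
    record lands in the low group.  Constant expression cannot be split.
    """
    expr = cohort["expression"].to_numpy(dtype=float)
    cut = float(np.quantile(expr, quantile))
    labels = np.where(expr > cut, "high", "low")
    if len(set(labels)) < 2:
        raise ValueError("cannot split: expression values admit no two groups")
    return pd.Series(labels, index=cohort.index, name="group")


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns a step-function table with one row per distinct event time (plus
    the t = 0 anchor at S = 1): columns ``time``, ``n_at_risk``, ``n_events``
    and ``survival``.  Censored records shrink the risk set without a step.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValueError("survival times must be >= 0")
    rows = [(0.0, len(t), 0, 1.0)]
    s = 1.0
    for ti in np.unique(t[e == 1]):
        n_risk = int((t >= ti).sum())
        d = int(((t == ti) & (e == 1)).sum())
        s *= 1.0 - d / n_risk
        rows.append((float(ti), n_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


@dataclasses.dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    hr: float  # (O_a/E_a)/(O_b/E_b); NaN when undefined
    observed: tuple[float, float]
    expected: tuple[float, float]


def logrank(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Mantel-Haenszel log-rank test of two samples plus the O/E hazard ratio.

    At each pooled event time the observed events in group A are compared to
    the expectation under the common-hazard null, with the hypergeometric
    variance (tie-aware).  The hazard ratio is directional: group A relative
    to group B.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("logrank requires two non-empty groups")

    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    oa = ea.sum()
    ob = eb.sum()
    expected_a = 0.0
    var = 0.0
    for ti in event_times:
        na = (ta >= ti).sum()
        nb = (tb >= ti).sum()
        n = na + nb
        da = ((ta == ti) & (ea == 1)).sum()
        db = ((tb == ti) & (eb == 1)).sum()
        d = da + db
        expected_a += d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if event_times.size == 0 or var == 0.0:
        hr = float("nan")
        return LogrankResult(0.0, 1.0, hr, (float(oa), float(ob)),
                             (float(expected_a), float(oa + ob - expected_a)))
    expected_b = (oa + ob) - expected_a
    chi2 = float((oa - expected_a) ** 2 / var)
    p = float(stats.chi2.sf(chi2, df=1))
    if ob > 0 and expected_a > 0 and expected_b > 0 and oa > 0:
        hr = float((oa / expected_a) / (ob / expected_b))
    else:
        hr = float("nan")
    return LogrankResult(
        chi2, p, hr, (float(oa), float(ob)), (float(expected_a), float(expected_b))
    )


@dataclasses.dataclass
class KMResult:
    """Full output of one stratified survival analysis."""

    n_high: int
    n_low: int
    events_high: int
    events_low: int
    chi2: float
    p: float
    hr: float  # high vs low
    curve_high: pd.DataFrame
    curve_low: pd.DataFrame
    dropped: dict[str, int]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": ["high", "low"],
                "n": [self.n_high, self.n_low],
                "events": [self.events_high, self.events_low],
                "chi2": [self.chi2] * 2,
                "p": [self.p] * 2,
                "hr_high_vs_low": [self.hr] * 2,
            }
        )


def analyze_cohort(
    cohort: pd.DataFrame,
    quantile: float = 0.5,
    min_time: float = MIN_FOLLOWUP_DAYS,
) -> KMResult:
    """clean -> median split -> KM curves -> log-rank, high vs low."""
    cleaned, dropped = clean_cohort(cohort, min_time=min_time)
    if cleaned.empty:
        raise ValueError("no records survive the cleaning filters")
    groups = split_by_expression(cleaned, quantile=quantile)
    hi = cleaned[groups == "high"]
    lo = cleaned[groups == "low"]
    lr = logrank(hi["time"], hi["event"], lo["time"], lo["event"])
    return KMResult(
        n_high=len(hi),
        n_low=len(lo),
        events_high=int(hi["event"].sum()),
        events_low=int(lo["event"].sum()),
        chi2=lr.chi2,
        p=lr.p,
        hr=lr.hr,
        curve_high=km_curve(hi["time"], hi["event"]),
        curve_low=km_curve(lo["time"], lo["event"]),
        dropped=dropped,
    )


def subgroup_analysis(
    cohort: pd.DataFrame,
    filters: Mapping[str, object],
    min_size: int = 10,
    quantile: float = 0.5,
    min_time: float = MIN_FOLLOWUP_DAYS,
) -> KMResult:
    """Stratified analysis restricted to a covariate-defined subgroup.

    *filters* maps covariate column -> required value (e.g. ``{"er": 1}``
    for the ER-positive subgroup).  Refuses subgroups smaller than
    *min_size* after filtering and cleaning.
    """
    sub = cohort
    for col, value in filters.items():
        if col not in sub.columns:
            raise ValueError(f"covariate {col!r} not in cohort")
        sub = sub[sub[col] == value]
    cleaned, _ = clean_cohort(sub, min_time=min_time)
    if len(cleaned) < min_size:
        raise ValueError(
            f"subgroup {dict(filters)!r} has only {len(cleaned)} analyzable "
            f"records (minimum {min_size})"
        )
    return analyze_cohort(sub, quantile=quantile, min_time=min_time)
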