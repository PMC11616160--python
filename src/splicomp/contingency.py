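"""Contingency-table and group-comparison statistics.

Pearson chi-square for r x c association, Fisher's exact test for 2 x 2
tables with the conditional-MLE odds ratio and its exact confidence
interval, and one-way ANOVA.  The exact odds ratio is the noncentral
hypergeometric conditional MLE (not the sample cross-product ratio), the
convention matched by exact confidence intervals obtained by inverting the
conditional test at the 2.5% tails; zero cells yield 0 or infinite bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    dropped_rows: list = None
    dropped_cols: list = None


@dataclass
class ExactTestResult:
    p_two_sided: float
    odds_ratio_cmle: float  # may be 0 or inf for boundary tables
    ci_low: float
    ci_high: float
    method: str = "fisher_exact_conditional"


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


def _as_int_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table entries must be integers")
    arr = np.round(arr).astype(np.int64)
    if (arr < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    return arr


def chi_square_test(table) -> ChiSquareResult:
    """Pearson chi-square test of association for an r x c table.

    Statistic sum (O - E)^2 / E with expectations from the margins;
    df = (r-1)(c-1); p from the chi-square upper tail.  Rows or columns
    with zero margin carry no information and are dropped with a warning
    record before testing.
    """
    arr = _as_int_table(table)
    row_keep = arr.sum(axis=1) > 0
    col_keep = arr.sum(axis=0) > 0
    dropped_rows = list(np.flatnonzero(~row_keep))
    dropped_cols = list(np.flatnonzero(~col_keep))
    arr = arr[np.ix_(row_keep, col_keep)]
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns with positive margins")
    n = arr.sum()
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n
    statistic = float(((arr - expected) ** 2 / expected).sum())
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    p = chi_square_sf(statistic, df)
    return ChiSquareResult(statistic, df, p, dropped_rows, dropped_cols)


def chi_square_sf(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability (regularized incomplete gamma)."""
    if statistic < 0 or df < 1:
        raise ValueError("statistic must be >= 0 and df >= 1")
    return float(stats.chi2.sf(statistic, df))


def fisher_exact_2x2(table) -> ExactTestResult:
    """Fisher's exact test for a 2 x 2 table.

    Two-sided p sums hypergeometric point probabilities no larger than the
    observed one (with a small relative tolerance); the odds ratio is the
    conditional MLE under the noncentral hypergeometric likelihood, and the
    95% CI inverts the exact conditional test at the 2.5% tails.  Tables
    with an empty row or column are degenerate: p = 1 with 0/inf bounds.
    """
    arr = _as_int_table(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 needs a 2 x 2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return ExactTestResult(1.0, np.nan, 0.0, np.inf, method="degenerate")
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    res = _cmle_odds_ratio(arr, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return ExactTestResult(float(p), float(res.statistic), float(ci.low), float(ci.high))


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """One-way ANOVA from per-sample values and group labels.

    Standard between/within decomposition: F = MS_between / MS_within with
    df (g-1, N-g); p from the F upper tail.  Every group needs >= 2 values.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    labels = sorted(set(groups.tolist()), key=str)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = []
    for lab in labels:
        vals = values[groups == lab]
        if len(vals) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
        samples.append(vals)
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in samples)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in samples)
    df_between = len(labels) - 1
    df_within = len(values) - len(labels)
    if ss_within == 0:
        # degenerate: identical within-group values
        f = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), df_between, df_within, p)
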