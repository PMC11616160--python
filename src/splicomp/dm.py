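"""Dirichlet-multinomial differential-splicing test.

Per intron group, the spliced-read counts of a sample are modelled as
multinomial with proportions drawn from a Dirichlet(alpha), which allows
extra-multinomial between-sample variability in splicing ratios (smaller
total concentration = more dispersion).  Differential splicing between two
conditions is a likelihood-ratio test: the null fits one alpha to the
pooled samples, the alternative one alpha per condition, and

    LRT = 2 (ll_cond1 + ll_cond2 - ll_pooled)  ~  chi-square(k)

asymptotically, k being the number of introns in the group (2k free
parameters under the alternative minus k under the null).  The multinomial
coefficient is omitted from every log-likelihood; it depends only on the
counts and cancels in the ratio.

Maximum likelihood uses Minka's fixed-point iteration

    alpha_k <- alpha_k * sum_j [psi(n_jk + alpha_k) - psi(alpha_k)]
                       / sum_j [psi(N_j + A) - psi(A)],     A = sum(alpha)

with a method-of-moments start; each step increases the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

_EPS_ALPHA = 1e-8


@dataclass
class DMFit:
    alpha: np.ndarray
    loglik: float
    n_iterations: int
    converged: bool
    boundary: bool = False  # some component saw no reads; its alpha pinned at epsilon


@dataclass
class DMTestResult:
    group_id: str
    k: int
    lrt_stat: float
    df: int
    p_value: float
    fdr: float = np.nan
    delta_psi: Optional[np.ndarray] = None  # condition-1 minus condition-2 mean PSI
    mean_psi_cond1: Optional[np.ndarray] = None
    mean_psi_cond2: Optional[np.ndarray] = None
    skipped_reason: Optional[str] = None


def _clean_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError("counts must be a samples x k table")
    if (arr < 0).any() or not np.all(np.isfinite(arr)):
        raise ValueError("counts must be finite and non-negative")
    return arr[arr.sum(axis=1) > 0]  # rows with total 0 carry no information


def loglik_dm(alpha, counts) -> float:
    """Dirichlet-multinomial log-likelihood, multinomial coefficient excluded.

    Sums over samples (rows of ``counts``); rows with total 0 are skipped.
    For a single sample with counts n and total N:

        ln Gamma(A) - ln Gamma(N + A) + sum_k [ln Gamma(n_k + a_k) - ln Gamma(a_k)]
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or (alpha <= 0).any() or not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be a vector of positive finite concentrations")
    arr = _clean_counts(counts)
    if arr.shape[1] != alpha.shape[0]:
        raise ValueError("alpha length does not match count columns")
    if arr.shape[0] == 0:
        return 0.0
    total_alpha = alpha.sum()
    totals = arr.sum(axis=1)
    ll = (
        gammaln(total_alpha) - gammaln(totals + total_alpha)
        + (gammaln(arr + alpha) - gammaln(alpha)).sum(axis=1)
    )
    return float(ll.sum())


def _moment_start(arr: np.ndarray) -> np.ndarray:
    """Method-of-moments alpha: mean proportions scaled by a moment-matched
    precision; falls back to precision k when moments are degenerate."""
    k = arr.shape[1]
    props = arr / arr.sum(axis=1, keepdims=True)
    mean_p = props.mean(axis=0)
    var_p = props.var(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        precisions = mean_p * (1 - mean_p) / var_p - 1.0
    precisions = precisions[np.isfinite(precisions) & (precisions > 0)]
    precision = float(np.median(precisions)) if precisions.size else float(k)
    precision = min(max(precision, 1e-2), 1e6)
    return np.maximum(mean_p * precision, _EPS_ALPHA)


def fit_dm(counts, tol: float = 1e-8, max_iter: int = 1000) -> DMFit:
    """Maximum-likelihood Dirichlet-multinomial fit by fixed-point iteration.

    Convergence is declared when the max change in log(alpha) drops below
    ``tol``.  Components that receive no reads in any sample sit on the
    likelihood boundary (alpha -> 0); they are pinned at a small epsilon and
    flagged.
    """
    arr = _clean_counts(counts)
    if arr.shape[0] < 1 or arr.shape[1] < 2:
        raise ValueError("need >=1 sample with reads and k >= 2 introns")
    col_seen = arr.sum(axis=0) > 0
    boundary = not col_seen.all()
    alpha = _moment_start(arr)
    totals = arr.sum(axis=1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        total_alpha = alpha.sum()
        denom = (digamma(totals + total_alpha) - digamma(total_alpha)).sum()
        numer = (digamma(arr + alpha) - digamma(alpha)).sum(axis=0)
        new_alpha = alpha * numer / denom
        new_alpha = np.maximum(new_alpha, _EPS_ALPHA)
        step = np.abs(np.log(new_alpha) - np.log(alpha)).max()
        alpha = new_alpha
        if step < tol:
            converged = True
            break
    return DMFit(
        alpha=alpha,
        loglik=loglik_dm(alpha, arr),
        n_iterations=it,
        converged=converged,
        boundary=boundary,
    )


def _mean_psi(arr: np.ndarray) -> np.ndarray:
    props = arr / arr.sum(axis=1, keepdims=True)
    return props.mean(axis=0)


def lrt_test(
    counts_cond1,
    counts_cond2,
    group_id: str = "",
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> DMTestResult:
    """Two-condition Dirichlet-multinomial likelihood-ratio test for a group.

    Null: one alpha over the pooled samples; alternative: one alpha per
    condition.  Tiny negative statistics (numerical) are clipped to zero;
    the p-value is the chi-square(k) upper tail.  ``delta_psi`` is the
    difference of per-condition mean observed PSI (cond1 - cond2).
    """
    arr1 = _clean_counts(counts_cond1)
    arr2 = _clean_counts(counts_cond2)
    k = max(arr1.shape[1] if arr1.size else 0, arr2.shape[1] if arr2.size else 0)
    if arr1.shape[0] < 2 or arr2.shape[0] < 2:
        return DMTestResult(
            group_id, k, np.nan, k, np.nan,
            skipped_reason="fewer than 2 usable samples in a condition",
        )
    if arr1.shape[1] != arr2.shape[1]:
        raise ValueError("conditions disagree on the number of introns")
    fit1 = fit_dm(arr1, tol=tol, max_iter=max_iter)
    fit2 = fit_dm(arr2, tol=tol, max_iter=max_iter)
    fit0 = fit_dm(np.vstack([arr1, arr2]), tol=tol, max_iter=max_iter)
    stat = 2.0 * (fit1.loglik + fit2.loglik - fit0.loglik)
    stat = max(stat, 0.0)
    p = float(chi2.sf(stat, df=k))
    m1, m2 = _mean_psi(arr1), _mean_psi(arr2)
    return DMTestResult(
        group_id=group_id,
        k=k,
        lrt_stat=stat,
        df=k,
        p_value=p,
        delta_psi=m1 - m2,
        mean_psi_cond1=m1,
        mean_psi_cond2=m2,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; NaN entries propagate as NaN."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        valid = p[mask]
        if (valid < 0).any() or (valid > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(valid, method="fdr_bh")[1]
    return out


def dm_test_groups(
    psi_members: dict[str, list],
    junctions,
    sample_condition: pd.Series,
    min_group_reads: int = 10,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.DataFrame:
    """Run the DM-LRT over every eligible group of a junction matrix.

    ``sample_condition`` maps sample id to one of exactly two condition
    labels.  Per group, samples whose total reads fall below
    ``min_group_reads`` are dropped from that group's test (not imputed).
    Returns a tidy table with BH-FDR across tested groups.
    """
    conditions = sorted(sample_condition.unique())
    if len(conditions) != 2:
        raise ValueError(f"exactly 2 conditions required, got {conditions}")
    index = junctions.intron_index
    cols1 = [junctions.samples.index(s) for s in sample_condition.index
             if sample_condition[s] == conditions[0]]
    cols2 = [junctions.samples.index(s) for s in sample_condition.index
             if sample_condition[s] == conditions[1]]
    records = []
    for gid, members in psi_members.items():
        rows = [index[key] for key in members]
        sub = junctions.counts[np.ix_(rows, cols1 + cols2)].T.astype(float)
        a1, a2 = sub[: len(cols1)], sub[len(cols1):]
        keep1 = a1[a1.sum(axis=1) >= min_group_reads]
        keep2 = a2[a2.sum(axis=1) >= min_group_reads]
        res = lrt_test(keep1, keep2, group_id=gid, tol=tol, max_iter=max_iter) \
            if (len(keep1) >= 2 and len(keep2) >= 2) else DMTestResult(
                gid, len(members), np.nan, len(members), np.nan,
                skipped_reason="fewer than 2 usable samples in a condition")
        records.append(res)
    frame = pd.DataFrame(
        {
            "group": [r.group_id for r in records],
            "k": [r.k for r in records],
            "lrt_stat": [r.lrt_stat for r in records],
            "df": [r.df for r in records],
            "p": [r.p_value for r in records],
            "delta_psi": [
                ";".join(f"{d:.6g}" for d in r.delta_psi) if r.delta_psi is not None else ""
                for r in records
            ],
            "mean_psi_cond1": [
                ";".join(f"{d:.6g}" for d in r.mean_psi_cond1) if r.mean_psi_cond1 is not None else ""
                for r in records
            ],
            "mean_psi_cond2": [
                ";".join(f"{d:.6g}" for d in r.mean_psi_cond2) if r.mean_psi_cond2 is not None else ""
                for r in records
            ],
            "skipped_reason": [r.skipped_reason or "" for r in records],
        }
    )
    frame["fdr"] = bh_adjust(frame["p"].to_numpy())
    return frame
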