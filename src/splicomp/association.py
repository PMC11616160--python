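"""Complexity-expression correlation profiling and depth diagnostics.

Per-sample aggregate splicing complexity is correlated (Spearman) with the
expression of every gene across samples; genes whose expression tracks
complexity positively are expected for depth reasons alone, so the
anti-correlated tail is the interesting one.  A read-depth diagnostic
correlates each sample's total junction reads with its aggregate s, since
shallow samples systematically under-detect rare splice forms and hence
score lower complexity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


def normalize_expression(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudocount.

    ``log2((count + pc) / (libsize + 2 pc) * 1e6)`` per gene and sample.
    Samples with zero library size are excluded with a warning.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("expression counts must be non-negative")
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        warnings.warn(f"excluding zero-library samples: {list(zero.index)}")
        counts = counts.drop(columns=zero.index)
        libsize = libsize.drop(zero.index)
    return np.log2((counts + pseudocount).div(libsize + 2 * pseudocount, axis=1) * 1e6)


@dataclass
class CorrelationProfile:
    """Per-gene Spearman rho/p of expression vs aggregate complexity."""

    table: pd.DataFrame  # index gene, columns rho, p, n_used


def spearman_profile(expr: pd.DataFrame, aggregate_s: pd.Series) -> CorrelationProfile:
    """Midrank Spearman correlation of each gene's expression with aggregate s.

    Samples missing an aggregate are excluded pairwise; genes with zero
    expression variance get a missing rho.  Requires >= 4 overlapping
    samples.
    """
    common = [s for s in expr.columns if s in aggregate_s.index and np.isfinite(aggregate_s[s])]
    if len(common) < 4:
        raise ValueError(f"need >= 4 overlapping samples with defined aggregate, got {len(common)}")
    x = expr[common].to_numpy(dtype=float)
    s = aggregate_s[common].to_numpy(dtype=float)
    rho = np.full(x.shape[0], np.nan)
    pval = np.full(x.shape[0], np.nan)
    varying = x.std(axis=1) > 0
    if s.std() > 0 and varying.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in np.flatnonzero(varying):
                rho[i], pval[i] = spearmanr(x[i], s)
    table = pd.DataFrame(
        {"rho": rho, "p": pval, "n_used": len(common)}, index=expr.index
    )
    table.index.name = "gene"
    return CorrelationProfile(table)


def depth_diagnostic(junctions, aggregate_s: pd.Series) -> dict:
    """Spearman association between per-sample total junction reads and s.

    Returns the correlation and the per-sample table (for export/plotting).
    Zero-variance aggregate yields a missing rho.
    """
    totals = junctions.total_reads_per_sample()
    common = [s for s in totals.index if s in aggregate_s.index and np.isfinite(aggregate_s[s])]
    table = pd.DataFrame(
        {"total_reads": totals[common], "aggregate_s": aggregate_s[common]}
    )
    table.index.name = "sample"
    if len(common) < 3 or table["aggregate_s"].std() == 0 or table["total_reads"].std() == 0:
        return {"rho": np.nan, "p": np.nan, "table": table}
    rho, p = spearmanr(table["total_reads"], table["aggregate_s"])
    return {"rho": float(rho), "p": float(p), "table": table}


def rank_genes(profile: CorrelationProfile, direction: str = "anti") -> list[str]:
    """Order genes by rho: ascending for ``anti`` (most negative first),
    descending for ``positive``.  Missing rho sorts last; ties break by
    gene id."""
    if direction not in ("anti", "positive"):
        raise ValueError("direction must be 'anti' or 'positive'")
    table = profile.table
    if table.empty or table["rho"].isna().all():
        warnings.warn("correlation profile has no defined rho values")
        return []
    defined = table["rho"].dropna()
    sign = 1.0 if direction == "anti" else -1.0
    ordered = sorted(defined.index, key=lambda g: (sign * defined[g], g))
    missing = sorted(set(table.index) - set(defined.index))
    return list(ordered) + missing
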