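"""Competitive Wilcoxon rank-sum gene-set enrichment.

Given any per-gene ranking statistic (a complexity-expression correlation,
a differential-expression statistic, ...), each gene set's members are
compared against all non-members by the Wilcoxon rank-sum test: the sum of
member midranks against its null over random subsets of the same size.
Small sets in small universes use the exact null distribution (dynamic
programming over midrank sums); otherwise a normal approximation with tie
and continuity corrections applies.  Direction is Up when members out-rank
non-members on average.  This is the plain competitive test: it does not
adjust for inter-gene correlation and is anti-conservative when member
genes are co-expressed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb, erf, sqrt
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from splicomp.dm import bh_adjust

EXACT_MAX_SET = 10
EXACT_MAX_UNIVERSE = 50


@dataclass
class GeneSetCollection:
    """GMT-shaped collection: set name -> (description, member genes)."""

    sets: dict[str, tuple[str, list[str]]]
    flagged_small: list[str]  # sets with < 2 genes as read

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]


@dataclass
class GeneSetResult:
    name: str
    n_in_universe: int
    z: float
    p: float
    direction: str  # "Up" | "Down"
    genes_present: list[str]
    fdr: float = np.nan
    method: str = "normal"  # "exact" | "normal"


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name, description, then tab-separated gene ids.

    Duplicate genes within a set are collapsed (order preserved); sets with
    fewer than two genes are kept but flagged.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    flagged: list[str] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: GMT rows need >= 3 tab-separated fields")
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}, line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = (description, genes)
            if len(genes) < 2:
                flagged.append(name)
    if not sets:
        warnings.warn(f"{path}: empty gene-set collection")
    return GeneSetCollection(sets, flagged)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (description, genes) in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def _exact_ranksum_tails(doubled_ranks: np.ndarray, member_mask: np.ndarray):
    """Exact null of the member rank-sum over equally likely subsets.

    Midranks are doubled to integers; a DP table counts size-j subsets by
    doubled rank-sum.  Returns (P(S <= obs), P(S >= obs)).
    """
    m = int(member_mask.sum())
    d = doubled_ranks.astype(np.int64)
    obs = int(d[member_mask].sum())
    max_sum = int(np.sort(d)[::-1][:m].sum())
    table = np.zeros((m + 1, max_sum + 1))
    table[0, 0] = 1.0
    for di in d:
        for j in range(m, 0, -1):
            table[j, di:] += table[j - 1, : max_sum + 1 - di]
    dist = table[m]
    total = comb(len(d), m)
    lower = dist[: obs + 1].sum() / total
    upper = dist[obs:].sum() / total
    return lower, upper


def _normal_tails(ranks: np.ndarray, member_mask: np.ndarray):
    """Normal approximation with tie correction and continuity correction.

    Returns (P(S <= obs), P(S >= obs), z) for the member rank-sum S.
    """
    n_total = len(ranks)
    m = int(member_mask.sum())
    n_rest = n_total - m
    obs = ranks[member_mask].sum()
    mean = m * (n_total + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts.astype(float) ** 3 - tie_counts).sum()
    var = m * n_rest / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
    if var <= 0:
        return 1.0, 1.0, 0.0
    sd = sqrt(var)
    z = (obs - mean) / sd

    def phi(x):
        return 0.5 * (1.0 + erf(x / sqrt(2.0)))

    upper = 1.0 - phi((obs - mean - 0.5) / sd)
    lower = phi((obs - mean + 0.5) / sd)
    return min(lower, 1.0), min(upper, 1.0), z


def wilcoxon_gene_set_test(
    stats: Mapping[str, float] | pd.Series,
    sets: GeneSetCollection,
    min_set_size: int = 5,
    alternative: str = "two_sided",
) -> list[GeneSetResult]:
    """Rank-sum test of each set's member statistics against non-members.

    The universe is every gene with a finite statistic.  Sets with fewer
    than ``min_set_size`` members in the universe are skipped (warning); a
    set covering the whole universe is an error.  ``alternative`` is
    ``two_sided`` (2 * min tail, capped at 1), ``up`` or ``down``.  The
    exact null is used when the set has <= 10 members in a universe of
    <= 50 genes.  BH-FDR is computed across the tested sets.
    """
    if alternative not in ("two_sided", "up", "down"):
        raise ValueError("alternative must be two_sided, up, or down")
    series = pd.Series(stats, dtype=float).dropna()
    universe = list(series.index)
    if len(universe) < 3:
        raise ValueError("statistic universe too small")
    values = series.to_numpy()
    ranks = rankdata(values)  # midranks
    doubled = np.round(2 * ranks).astype(np.int64)
    pos = {g: i for i, g in enumerate(universe)}

    results: list[GeneSetResult] = []
    for name in sets.sets:
        present = [g for g in sets.members(name) if g in pos]
        if len(present) < min_set_size:
            warnings.warn(f"set {name!r}: only {len(present)} members in universe; skipped")
            continue
        if len(present) == len(universe):
            raise ValueError(f"set {name!r} equals the whole statistic universe")
        mask = np.zeros(len(universe), dtype=bool)
        mask[[pos[g] for g in present]] = True
        m = len(present)
        mean_rank_members = ranks[mask].mean()
        mean_rank_rest = ranks[~mask].mean()
        direction = "Up" if mean_rank_members > mean_rank_rest else "Down"
        lower_n, upper_n, z = _normal_tails(ranks, mask)
        if m <= EXACT_MAX_SET and len(universe) <= EXACT_MAX_UNIVERSE:
            lower, upper = _exact_ranksum_tails(doubled, mask)
            method = "exact"
        else:
            lower, upper = lower_n, upper_n
            method = "normal"
        if alternative == "up":
            p = upper
        elif alternative == "down":
            p = lower
        else:
            p = min(1.0, 2.0 * min(lower, upper))
        results.append(
            GeneSetResult(
                name=name,
                n_in_universe=m,
                z=float(z),
                p=float(p),
                direction=direction,
                genes_present=present,
                method=method,
            )
        )
    fdrs = bh_adjust([r.p for r in results])
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
    return results


def report_table(
    results: Sequence[GeneSetResult],
    top_n: Optional[int] = None,
    path=None,
) -> pd.DataFrame:
    """Tabulate gene-set results (set, N, FDR, direction, genes).

    Sorted by FDR then p then set name; the genes column is
    semicolon-joined.  Writes a TSV when ``path`` is given.
    """
    if not results:
        raise ValueError("no gene-set results to report")
    ordered = sorted(results, key=lambda r: (r.fdr, r.p, r.name))
    if top_n is not None:
        ordered = ordered[: max(top_n, 0)]
    frame = pd.DataFrame(
        {
            "gene_set": [r.name for r in ordered],
            "n": [r.n_in_universe for r in ordered],
            "z": [r.z for r in ordered],
            "p": [r.p for r in ordered],
            "fdr": [r.fdr for r in ordered],
            "direction": [r.direction for r in ordered],
            "genes": [";".join(r.genes_present) for r in ordered],
        }
    )
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
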