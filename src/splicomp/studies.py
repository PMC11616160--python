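"""Cohort-level simulation studies: calibration, power, planted recovery.

These are the package's own verification experiments, exercised both by the
test suite and by ``scripts/acceptance.py``.  Each function is a complete
study driven by one seed: it generates its inputs with the synthetic-cohort
machinery, runs the relevant analysis route end to end, and returns the
summary quantity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from splicomp.association import normalize_expression, rank_genes, spearman_profile
from splicomp.core import (
    JunctionCountMatrix,
    aggregate_complexity,
    compute_psi,
    group_complexity,
)
from splicomp.dm import dm_test_groups, lrt_test
from splicomp.genesets import wilcoxon_gene_set_test
from splicomp.sim import SimConfig, simulate_cohort, simulate_null_group_counts


def dm_null_rejection_rate(
    seed: int,
    n_groups: int = 2000,
    n_per_condition: int = 20,
    mean_depth: float = 100.0,
    concentration: float = 5.0,
    k: int = 3,
    level: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Type-I error of the DM-LRT on null groups (shared alpha, two arms).

    Returns the rejection rate at ``level`` and the vector of p-values.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_groups)
    for i in range(n_groups):
        alpha = concentration * rng.dirichlet(np.full(k, 2.0))
        a = simulate_null_group_counts(rng, alpha, n_per_condition, mean_depth)
        b = simulate_null_group_counts(rng, alpha, n_per_condition, mean_depth)
        pvals[i] = lrt_test(a, b).p_value
    return float(np.mean(pvals < level)), pvals


def dm_power(
    seed: int,
    effect_delta_psi: float = 0.3,
    n_per_condition: int = 20,
    n_groups: int = 200,
    frac_differential: float = 0.1,
    fdr_level: float = 0.05,
) -> float:
    """Fraction of planted differential groups recovered at the FDR level."""
    cohort = simulate_cohort(
        SimConfig(
            n_samples_per_condition=n_per_condition,
            n_groups=n_groups,
            frac_differential_groups=frac_differential,
            effect_delta_psi=effect_delta_psi,
            n_genes=10,
            frac_complexity_linked_genes=0.1,
            planted_set_size=1,
            seed=seed,
        )
    )
    psi = compute_psi(cohort.junction_counts, cohort.truth_groups)
    table = dm_test_groups(psi.members, cohort.junction_counts, cohort.sample_sheet)
    hits = set(table.loc[table["fdr"] < fdr_level, "group"])
    truth = cohort.truth_differential
    return len(hits & truth) / len(truth)


def planted_gene_recovery(
    seed: int,
    n_replicates: int = 10,
    n_per_condition: int = 30,
    link_strength: float = -0.6,
    decile: float = 0.1,
) -> float:
    """Fraction of replicates whose planted anti-linked genes land, by median
    rank, in the bottom decile of the anti-correlation ordering."""
    hits = 0
    for r in range(n_replicates):
        cohort = simulate_cohort(
            SimConfig(
                n_samples_per_condition=n_per_condition,
                n_groups=100,
                link_strength=link_strength,
                seed=seed + r,
            )
        )
        profile = spearman_profile(
            normalize_expression(cohort.expression), cohort.aggregate_s
        )
        ranked = rank_genes(profile, "anti")
        position = {g: i for i, g in enumerate(ranked)}
        median_rank = np.median([position[g] for g in cohort.truth_linked_genes])
        hits += median_rank < decile * len(ranked)
    return hits / n_replicates


def thinning_effect(
    seed: int,
    n_replicates: int = 8,
    keep_fraction: float = 0.1,
) -> pd.DataFrame:
    """Aggregate s at full depth vs after binomial thinning, per replicate.

    Columns: ``full`` and ``thinned`` mean aggregate s.  Detection of rare
    splice forms needs depth, so thinning should not increase s.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_replicates):
        cohort = simulate_cohort(
            SimConfig(
                n_samples_per_condition=10,
                n_groups=100,
                frac_differential_groups=0.0,
                n_genes=10,
                frac_complexity_linked_genes=0.1,
                planted_set_size=1,
                seed=seed + r,
            )
        )
        jm = cohort.junction_counts
        thinned = JunctionCountMatrix(
            jm.introns, jm.samples, rng.binomial(jm.counts, keep_fraction)
        )
        full_s = aggregate_complexity(
            group_complexity(compute_psi(jm, cohort.truth_groups))
        )["aggregate_s"]
        thin_s = aggregate_complexity(
            group_complexity(compute_psi(thinned, cohort.truth_groups))
        )["aggregate_s"]
        rows.append((full_s.mean(), thin_s.mean()))
    return pd.DataFrame(rows, columns=["full", "thinned"])


def wilcoxon_null_pvalues(
    seed: int,
    n_draws: int = 500,
    universe_size: int = 500,
    set_size: int = 20,
) -> np.ndarray:
    """Two-sided gene-set p-values for random sets on exchangeable statistics."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_draws)
    for i in range(n_draws):
        values = rng.normal(size=universe_size)
        stats = pd.Series(values, index=[f"g{j}" for j in range(universe_size)])
        members = [f"g{j}" for j in rng.choice(universe_size, set_size, replace=False)]
        from splicomp.genesets import GeneSetCollection

        coll = GeneSetCollection({"R": ("", members)}, [])
        pvals[i] = wilcoxon_gene_set_test(stats, coll)[0].p
    return pvals


def planted_set_enrichment_fdr(seed: int, n_per_condition: int = 30) -> float:
    """FDR of the planted complexity-linked gene set in a full pipeline pass."""
    cohort = simulate_cohort(
        SimConfig(n_samples_per_condition=n_per_condition, n_groups=100, seed=seed)
    )
    profile = spearman_profile(
        normalize_expression(cohort.expression), cohort.aggregate_s
    )
    results = wilcoxon_gene_set_test(profile.table["rho"], cohort.gene_sets)
    by_name = {r.name: r for r in results}
    return by_name[cohort.planted_set_name].fdr
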