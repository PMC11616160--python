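import numpy as np
import pytest

from splicomp.core import IntronKey, JunctionCountMatrix
from splicomp.sim import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-condition cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(n_samples_per_condition=10, n_groups=60, seed=42))


@pytest.fixture
def three_intron_matrix():
    """Hand-built 3-intron, 2-sample junction matrix forming one group."""
    introns = [
        IntronKey("chr1", 100, 200, "+"),
        IntronKey("chr1", 100, 300, "+"),
        IntronKey("chr1", 250, 300, "+"),
    ]
    counts = np.array([[6, 0], [3, 0], [1, 12]])
    return JunctionCountMatrix(introns, ["a", "b"], counts)


def random_junction_matrix(rng, n_introns, n_samples=3, n_positions=12):
    """Random introns over a small coordinate pool to force endpoint sharing."""
    introns = set()
    while len(introns) < n_introns:
        chrom = rng.choice(["chr1", "chr2"])
        start, end = sorted(rng.choice(n_positions * 100, size=2, replace=False).tolist())
        strand = rng.choice(["+", "-", "."])
        introns.add(IntronKey(str(chrom), int(start), int(end) + 1, str(strand)))
    introns = sorted(introns)
    counts = rng.integers(0, 40, size=(len(introns), n_samples))
    return JunctionCountMatrix(introns, [f"s{i}" for i in range(n_samples)], counts)


def grouping_oracle(introns):
    """Brute-force transitive closure over pairwise shared endpoints."""
    n = len(introns)
    adj = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            a, b = introns[i], introns[j]
            adj[i][j] = (
                i == j
                or (
                    a.chrom == b.chrom
                    and a.strand == b.strand
                    and (a.start == b.start or a.end == b.end)
                )
            )
    for k in range(n):  # Floyd-Warshall closure
        for i in range(n):
            if adj[i][k]:
                for j in range(n):
                    if adj[k][j]:
                        adj[i][j] = True
    components = []
    seen = set()
    for i in range(n):
        if i in seen:
            continue
        comp = frozenset(j for j in range(n) if adj[i][j])
        seen |= comp
        components.append(frozenset(introns[j] for j in comp))
    return set(components)
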