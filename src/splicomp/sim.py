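"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a two-condition bulk RNA-seq cohort at the level the
pipeline consumes: per-sample junction counts organised into shared-endpoint
intron groups with Dirichlet-multinomial between-sample dispersion, a
negative-binomial gene-expression matrix in which a planted subset of genes
tracks each sample's realized aggregate splicing complexity, a two-group
outcome label (progressor / non-progressor), and a GMT collection containing
one planted enriched set plus uniform decoys.  Everything is driven by a
single master seed; each stage draws from its own labelled child stream so
adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from splicomp.core import (
    IntronKey,
    JunctionCountMatrix,
    IntronGroupSet,
    build_groups,
    compute_psi,
    group_complexity,
    aggregate_complexity,
    read_junctions,
)
from splicomp.genesets import GeneSetCollection, write_gmt

_CHROM = "chrS"
_GROUP_SPACING = 10_000
_INTRON_STEP = 100
# fixed stage labels for child random streams
_STAGE = {"proportions": 1, "counts": 2, "expression": 3, "gene_sets": 4}


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    Defaults describe a modest bulk RNA-seq study: 20 samples per outcome
    group, 3-intron splice-form groups at ~100 spliced reads each,
    Dirichlet precision 5 (substantial between-sample PSI variability), 10%
    of groups differential with a 0.3 shift of the primary isoform
    proportion, and 5% of 1000 genes linked to aggregate complexity at a
    target Spearman of -0.6.
    """

    n_samples_per_condition: int = 20
    n_groups: int = 200
    introns_per_group: int = 3
    mean_group_depth: float = 100.0
    dm_concentration: float = 5.0
    frac_differential_groups: float = 0.1
    effect_delta_psi: float = 0.3
    n_genes: int = 1000
    frac_complexity_linked_genes: float = 0.05
    link_strength: float = -0.6
    nb_dispersion: float = 0.1
    planted_set_size: int = 25
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_per_condition < 1 or self.n_groups < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        if self.introns_per_group < 2:
            raise ValueError("introns_per_group must be >= 2")
        if self.mean_group_depth <= 0 or self.dm_concentration <= 0 or self.nb_dispersion <= 0:
            raise ValueError("depth, concentration and dispersion must be positive")
        if not (0 <= self.frac_differential_groups <= 1):
            raise ValueError("frac_differential_groups must be in [0, 1]")
        if not (0 < self.effect_delta_psi < 1):
            raise ValueError("effect_delta_psi must be in (0, 1)")
        if not (0 <= self.frac_complexity_linked_genes <= 1):
            raise ValueError("frac_complexity_linked_genes must be in [0, 1]")
        if not (-1 <= self.link_strength <= 1):
            raise ValueError("link_strength must be in [-1, 1]")
        if self.planted_set_size < 1:
            raise ValueError("planted_set_size must be positive")
        n_linked = round(self.frac_complexity_linked_genes * self.n_genes)
        if self.frac_complexity_linked_genes > 0 and self.planted_set_size > n_linked:
            raise ValueError(
                f"planted_set_size {self.planted_set_size} exceeds the "
                f"{n_linked} complexity-linked genes"
            )


@dataclass
class SimulatedCohort:
    config: SimConfig
    junction_counts: JunctionCountMatrix
    truth_groups: IntronGroupSet
    truth_differential: set[str]
    expression: pd.DataFrame  # genes x samples integer counts
    truth_linked_genes: set[str]
    sample_sheet: pd.Series  # sample id -> condition label
    gene_sets: GeneSetCollection
    planted_set_name: str
    aggregate_s: pd.Series  # realized per-sample aggregate complexity
    group_alpha: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE[stage]]))


def _shift_primary(p: np.ndarray, delta: float) -> np.ndarray:
    """Shift the primary (largest) component by delta, renormalizing the rest.

    Shifts down when that keeps the proportion in (0,1), otherwise up; if
    neither direction keeps every proportion inside (0,1) the configuration
    is rejected.
    """
    i = int(np.argmax(p))
    for new_primary in (p[i] - delta, p[i] + delta):
        if 0 < new_primary < 1:
            out = p * (1 - new_primary) / (1 - p[i])
            out[i] = new_primary
            if (out > 0).all() and (out < 1).all():
                return out / out.sum()
    raise ValueError(
        f"effect_delta_psi={delta} pushes an expected proportion outside (0,1) "
        f"for base proportions {p}"
    )


def _group_ids(config: SimConfig) -> list[str]:
    return [f"{_CHROM}:{_GROUP_SPACING * (g + 1)}:+" for g in range(config.n_groups)]


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a complete cohort under ``config`` (deterministic in the seed).

    Per group g and sample j: proportions p ~ Dirichlet(alpha_g(condition)),
    counts ~ Multinomial(N_j, p) with N_j ~ Poisson(mean_group_depth).  For
    differential groups the condition-2 alpha has the primary component's
    expected proportion shifted by ``effect_delta_psi``.  Linked genes'
    log-expression follows a monotone (normal-scores) function of the
    sample's realized aggregate s, with latent correlation inflated by a
    first-order attenuation factor so the observed Spearman hits
    ``link_strength`` approximately in expectation.
    """
    config.validate()
    k = config.introns_per_group
    n_per = config.n_samples_per_condition
    samples = [f"S{j + 1:03d}" for j in range(2 * n_per)]
    conditions = ["non_progressor"] * n_per + ["progressor"] * n_per
    sample_sheet = pd.Series(conditions, index=samples, name="condition")

    # --- intron geometry: one window per group, members share the start ---
    introns: list[IntronKey] = []
    group_members: dict[str, list[IntronKey]] = {}
    gids = _group_ids(config)
    for g, gid in enumerate(gids):
        base = _GROUP_SPACING * (g + 1)
        members = [
            IntronKey(_CHROM, base, base + _INTRON_STEP * (i + 1), "+") for i in range(k)
        ]
        group_members[gid] = members
        introns.extend(members)

    # --- per-group concentrations ---
    rng_p = _stage_rng(config.seed, "proportions")
    base_props = rng_p.dirichlet(np.full(k, 2.0), size=config.n_groups)
    n_diff = round(config.frac_differential_groups * config.n_groups)
    diff_idx = set(
        rng_p.choice(config.n_groups, size=n_diff, replace=False).tolist()
    ) if n_diff else set()
    group_alpha: dict[str, dict[str, np.ndarray]] = {}
    for g, gid in enumerate(gids):
        p1 = base_props[g]
        p2 = _shift_primary(p1, config.effect_delta_psi) if g in diff_idx else p1
        group_alpha[gid] = {
            "non_progressor": config.dm_concentration * p1,
            "progressor": config.dm_concentration * p2,
        }
    truth_differential = {gids[g] for g in diff_idx}

    # --- junction counts ---
    rng_c = _stage_rng(config.seed, "counts")
    counts = np.zeros((len(introns), len(samples)), dtype=np.int64)
    for g, gid in enumerate(gids):
        row0 = g * k
        for j, cond in enumerate(conditions):
            n_reads = rng_c.poisson(config.mean_group_depth)
            if n_reads == 0:
                continue
            p = rng_c.dirichlet(group_alpha[gid][cond])
            counts[row0 : row0 + k, j] = rng_c.multinomial(n_reads, p)
    junctions = JunctionCountMatrix(introns, samples, counts)
    truth_groups = IntronGroupSet(group_members)

    # --- realized aggregate complexity ---
    psi = compute_psi(junctions, truth_groups, min_group_reads=10)
    agg = aggregate_complexity(group_complexity(psi), min_sample_fraction=0.5)
    aggregate_s = agg["aggregate_s"]

    # --- expression with planted complexity link ---
    rng_e = _stage_rng(config.seed, "expression")
    genes = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
    n_linked = round(config.frac_complexity_linked_genes * config.n_genes)
    linked_idx = (
        np.sort(rng_e.choice(config.n_genes, size=n_linked, replace=False))
        if n_linked
        else np.array([], dtype=int)
    )
    truth_linked = {genes[i] for i in linked_idx}

    s_vals = aggregate_s.reindex(samples).to_numpy(dtype=float)
    s_filled = np.where(np.isfinite(s_vals), s_vals, np.nanmedian(s_vals))
    order = pd.Series(s_filled).rank(method="average").to_numpy()
    z_s = _normal_scores(order)

    sig_scale = 1.0  # sd of the log-scale biological signal
    typical_mean = math.exp(4.0)
    extra_var = math.log1p(config.nb_dispersion) + 1.0 / typical_mean
    attenuation = sig_scale / math.sqrt(sig_scale**2 + extra_var)
    attenuation *= 0.955  # Spearman of a bivariate normal ~ (6/pi) asin(r/2)
    rho_lat = float(np.clip(config.link_strength / attenuation, -0.995, 0.995))

    base_mean = rng_e.lognormal(mean=4.0, sigma=1.0, size=config.n_genes)
    is_linked = np.zeros(config.n_genes, dtype=bool)
    is_linked[linked_idx] = True
    eps = rng_e.standard_normal((config.n_genes, len(samples)))
    latent = eps.copy()
    latent[is_linked] = rho_lat * z_s + math.sqrt(1 - rho_lat**2) * eps[is_linked]
    mu = base_mean[:, None] * np.exp(sig_scale * latent)
    shape = 1.0 / config.nb_dispersion
    lam = rng_e.gamma(shape, scale=mu / shape)
    expr = rng_e.poisson(lam).astype(np.int64)
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    # --- gene sets: one planted set from the linked genes, uniform decoys ---
    rng_g = _stage_rng(config.seed, "gene_sets")
    planted_name = "PLANTED_COMPLEXITY_LINKED"
    sets: dict[str, tuple[str, list[str]]] = {}
    if n_linked:
        planted = sorted(
            rng_g.choice(sorted(truth_linked), size=config.planted_set_size, replace=False)
        )
        sets[planted_name] = ("genes planted to track aggregate complexity", planted)
    for d in range(19):
        decoy = sorted(
            rng_g.choice(genes, size=min(config.planted_set_size, config.n_genes - 1),
                         replace=False)
        )
        sets[f"DECOY_{d + 1:02d}"] = ("uniformly drawn decoy set", decoy)
    gene_sets = GeneSetCollection(sets, [])

    return SimulatedCohort(
        config=config,
        junction_counts=junctions,
        truth_groups=truth_groups,
        truth_differential=truth_differential,
        expression=expression,
        truth_linked_genes=truth_linked,
        sample_sheet=sample_sheet,
        gene_sets=gene_sets,
        planted_set_name=planted_name if n_linked else "",
        aggregate_s=aggregate_s,
        group_alpha=group_alpha,
    )


def _normal_scores(ranks: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.ppf((ranks - 0.5) / len(ranks))


def simulate_null_group_counts(
    rng: np.random.Generator,
    alpha: np.ndarray,
    n_samples: int,
    mean_depth: float,
) -> np.ndarray:
    """Counts for one group of exchangeable samples (shared alpha).

    Convenience for calibration studies: rows are samples, columns introns.
    """
    k = len(alpha)
    out = np.zeros((n_samples, k), dtype=np.int64)
    for j in range(n_samples):
        n_reads = rng.poisson(mean_depth)
        if n_reads:
            out[j] = rng.multinomial(n_reads, rng.dirichlet(alpha))
    return out


def write_fixture(cohort: SimulatedCohort, directory, overwrite: bool = False) -> dict:
    """Write a cohort to disk in every supported input dialect.

    Emits the generic junction TSV, per-sample STAR ``SJ.out.tab`` files,
    the expression TSV, the sample sheet, the GMT collection, and a YAML
    truth manifest.  Refuses to write into a non-empty directory unless
    ``overwrite`` is set.  Files round-trip losslessly through the package
    readers.
    """
    if not cohort.truth_groups.groups:
        raise ValueError("refusing to write an empty cohort (0 groups)")
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty; pass overwrite=True to replace")
    (directory / "star").mkdir(parents=True, exist_ok=True)

    jm = cohort.junction_counts
    generic = directory / "junctions.tsv"
    with open(generic, "w") as fh:
        fh.write("\t".join(["chrom", "start", "end", "strand", *jm.samples]) + "\n")
        for i, key in enumerate(jm.introns):
            row = [key.chrom, str(key.start), str(key.end), key.strand]
            row += [str(int(c)) for c in jm.counts[i]]
            fh.write("\t".join(row) + "\n")

    star_code = {"+": "1", "-": "2", ".": "0"}
    star_files = []
    for j, sample in enumerate(jm.samples):
        path = directory / "star" / f"{sample}.SJ.out.tab"
        star_files.append(str(path.relative_to(directory)))
        with open(path, "w") as fh:
            for i, key in enumerate(jm.introns):
                fh.write(
                    "\t".join(
                        [
                            key.chrom,
                            str(key.start + 1),  # 1-based inclusive
                            str(key.end),
                            star_code[key.strand],
                            "0", "0",
                            str(int(jm.counts[i, j])),
                            "0", "0",
                        ]
                    )
                    + "\n"
                )

    expr_path = directory / "expression.tsv"
    out = cohort.expression.copy()
    out.index.name = "gene"
    out.to_csv(expr_path, sep="\t")

    sheet_path = directory / "samples.tsv"
    sheet = cohort.sample_sheet.rename_axis("sample").reset_index()
    sheet.to_csv(sheet_path, sep="\t", index=False)

    gmt_path = directory / "gene_sets.gmt"
    write_gmt(cohort.gene_sets, gmt_path)

    manifest = {
        "config": asdict(cohort.config),
        "files": {
            "junctions_generic_tsv": "junctions.tsv",
            "junctions_star_sj": star_files,
            "expression_tsv": "expression.tsv",
            "sample_sheet_tsv": "samples.tsv",
            "gene_sets_gmt": "gene_sets.gmt",
        },
        "planted_set_name": cohort.planted_set_name,
        "truth_differential_groups": sorted(cohort.truth_differential),
        "truth_linked_genes": sorted(cohort.truth_linked_genes),
    }
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def read_fixture_junctions(directory, dialect: str = "generic_tsv") -> JunctionCountMatrix:
    """Read a written fixture back through the standard readers."""
    directory = Path(directory)
    if dialect == "generic_tsv":
        return read_junctions(directory / "junctions.tsv", dialect="generic_tsv")
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    paths = [directory / p for p in manifest["files"]["junctions_star_sj"]]
    return read_junctions(paths, dialect="star_sj")
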