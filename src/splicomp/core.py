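"""Intron groups, PSI quantification, and the splicing-complexity score.

An "intron" is a genomic segment between two exons, identified from spliced
read alignments and represented here by (chrom, start, end, strand) with
0-based half-open coordinates.  Introns that share a 5' or a 3' endpoint on
the same chromosome and strand describe mutually exclusive splice forms and
are grouped together; within a group, each intron's PSI is its read count
divided by the group total, and the group's complexity in a sample is

    s = 1 - (PSI_max - PSI_avg),

which lies in [1/k, 1] for a k-intron group: 1 when all forms are used
equally, 1/k when a single form carries every read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")
_STAR_STRAND = {"0": ".", "1": "+", "2": "-"}


class IntronKey(NamedTuple):
    """One intron; coordinates are 0-based half-open, strand in {+, -, .}."""

    chrom: str
    start: int
    end: int
    strand: str

    def validate(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid intron coordinates {self}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r} in {self}")


@dataclass
class JunctionCountMatrix:
    """Introns x samples table of spliced-read counts (y_i per sample)."""

    introns: list[IntronKey]
    samples: list[str]
    counts: np.ndarray  # shape (n_introns, n_samples), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.introns), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.introns)} introns x {len(self.samples)} samples"
            )
        if self.counts.size and (
            not np.issubdtype(self.counts.dtype, np.integer) or (self.counts < 0).any()
        ):
            raise ValueError("junction counts must be non-negative integers")
        if len(set(self.introns)) != len(self.introns):
            raise ValueError("duplicate intron keys in junction matrix")
        for key in self.introns:
            key.validate()

    @property
    def intron_index(self) -> dict[IntronKey, int]:
        return {key: i for i, key in enumerate(self.introns)}

    def total_reads_per_sample(self) -> pd.Series:
        """Total spliced reads per sample (the depth-diagnostic covariate)."""
        return pd.Series(self.counts.sum(axis=0), index=self.samples, name="total_reads")

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.introns, names=["chrom", "start", "end", "strand"])
        return pd.DataFrame(self.counts, index=idx, columns=self.samples)

    def subset_samples(self, samples: Sequence[str]) -> "JunctionCountMatrix":
        pos = [self.samples.index(s) for s in samples]
        return JunctionCountMatrix(list(self.introns), list(samples), self.counts[:, pos].copy())


@dataclass
class IntronGroupSet:
    """Partition of introns into shared-endpoint groups.

    Group ids are deterministic: ``{chrom}:{leftmost start}:{strand}``.
    Groups are ordered by (chrom, leftmost start, leftmost end); members
    within a group by (start, end).
    """

    groups: dict[str, list[IntronKey]]

    def __post_init__(self) -> None:
        seen: set[IntronKey] = set()
        for gid, members in self.groups.items():
            if not members:
                raise ValueError(f"group {gid} has no members")
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"introns assigned to more than one group: {sorted(overlap)}")
            seen.update(members)

    def eligible(self) -> dict[str, list[IntronKey]]:
        """Groups with >= 2 members; singletons carry no splicing signal."""
        return {gid: m for gid, m in self.groups.items() if len(m) >= 2}

    def group_of(self) -> dict[IntronKey, str]:
        return {key: gid for gid, members in self.groups.items() for key in members}


@dataclass
class PsiTensor:
    """Per-group, per-sample PSI vectors over member introns.

    ``psi[gid]`` is a (k x n_samples) float array; a sample whose group total
    fell below the read threshold is a column of NaN.  Only eligible groups
    (>= 2 members) appear; singleton groups are always missing.
    """

    samples: list[str]
    members: dict[str, list[IntronKey]]
    psi: dict[str, np.ndarray]

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for gid, mat in self.psi.items():
            for i, key in enumerate(self.members[gid]):
                for j, sample in enumerate(self.samples):
                    rows.append((gid, f"{key.chrom}:{key.start}-{key.end}:{key.strand}",
                                 sample, mat[i, j]))
        return pd.DataFrame(rows, columns=["group", "intron", "sample", "psi"])


@dataclass
class ComplexityMatrix:
    """Group x sample complexity scores s = 1 - (PSI_max - PSI_avg)."""

    s_values: pd.DataFrame  # groups x samples, NaN = missing
    group_sizes: dict[str, int]


def _parse_int(token: str, what: str, path: Path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ValueError(f"{path}, line {lineno}: malformed {what} {token!r}") from None


def _read_star_sj(path: Path) -> dict[IntronKey, int]:
    """One STAR SJ.out.tab file: 1-based inclusive coords, strand code 0/1/2.

    Uses the uniquely-mapping read count (column 7).
    """
    counts: dict[IntronKey, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}, line {lineno}: expected >=7 tab-separated fields")
            chrom = fields[0]
            start1 = _parse_int(fields[1], "start", path, lineno)
            end1 = _parse_int(fields[2], "end", path, lineno)
            strand = _STAR_STRAND.get(fields[3])
            if strand is None:
                raise ValueError(f"{path}, line {lineno}: bad strand code {fields[3]!r}")
            n_reads = _parse_int(fields[6], "read count", path, lineno)
            if n_reads < 0:
                raise ValueError(f"{path}, line {lineno}: negative count {n_reads}")
            key = IntronKey(chrom, start1 - 1, end1, strand)
            counts[key] = counts.get(key, 0) + n_reads
    return counts


def _star_sample_name(path: Path) -> str:
    name = path.name
    for suffix in (".SJ.out.tab", ".sj.out.tab", ".tab", ".tsv"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def _read_generic_tsv(path: Path) -> JunctionCountMatrix:
    """Multi-sample junction TSV: chrom, start, end, strand, then one column
    per sample; coordinates already 0-based half-open."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 5 or header[:4] != ["chrom", "start", "end", "strand"]:
            raise ValueError(
                f"{path}, line 1: expected header 'chrom\\tstart\\tend\\tstrand\\t<samples...>'"
            )
        samples = header[4:]
        if len(set(samples)) != len(samples):
            raise ValueError(f"{path}: duplicate sample ids in header")
        introns: list[IntronKey] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}, line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            strand = fields[3]
            if strand not in STRANDS:
                raise ValueError(f"{path}, line {lineno}: bad strand {strand!r}")
            key = IntronKey(
                fields[0],
                _parse_int(fields[1], "start", path, lineno),
                _parse_int(fields[2], "end", path, lineno),
                strand,
            )
            counts = [_parse_int(tok, "count", path, lineno) for tok in fields[4:]]
            if any(c < 0 for c in counts):
                raise ValueError(f"{path}, line {lineno}: negative count")
            introns.append(key)
            rows.append(counts)
    return JunctionCountMatrix(introns, samples, np.asarray(rows, dtype=np.int64).reshape(len(introns), len(samples)))


def read_junctions(path, dialect: str = "generic_tsv") -> JunctionCountMatrix:
    """Read junction counts into a JunctionCountMatrix.

    Parameters
    ----------
    path
        For ``generic_tsv``: one multi-sample TSV. For ``star_sj``: a single
        STAR ``SJ.out.tab`` file or a sequence of per-sample files; sample
        ids are taken from the file names and the files are merged by intron
        with absent entries filled as 0.
    dialect
        ``"star_sj"`` (1-based inclusive coordinates, strand codes 0/1/2) or
        ``"generic_tsv"`` (0-based half-open, explicit header).
    """
    if dialect == "generic_tsv":
        if isinstance(path, (list, tuple)):
            raise ValueError("generic_tsv dialect takes a single file")
        return _read_generic_tsv(Path(path))
    if dialect != "star_sj":
        raise ValueError(f"unknown dialect {dialect!r}; use 'star_sj' or 'generic_tsv'")

    paths = [Path(p) for p in (path if isinstance(path, (list, tuple)) else [path])]
    samples = [_star_sample_name(p) for p in paths]
    if len(set(samples)) != len(samples):
        raise ValueError(f"inconsistent sample ids across STAR files: duplicates in {samples}")
    per_sample = [_read_star_sj(p) for p in paths]
    all_keys = sorted({k for d in per_sample for k in d})
    counts = np.zeros((len(all_keys), len(samples)), dtype=np.int64)
    for j, d in enumerate(per_sample):
        for i, key in enumerate(all_keys):
            if key in d:
                counts[i, j] = d[key]
    return JunctionCountMatrix(all_keys, samples, counts)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def build_groups(junctions: JunctionCountMatrix) -> IntronGroupSet:
    """Partition introns into connected components under shared endpoints.

    Two introns are linked when they lie on the same chromosome and strand
    and share either their start (5' on the + strand) or their end
    coordinate; groups are the transitive closure of that relation, found by
    union-find.  Grouping is strand-stratified (unknown strand '.' is its
    own stratum) so that antisense junctions never form chimeric groups.
    Singleton groups are retained; downstream PSI/complexity skip them.
    """
    if not junctions.introns:
        raise ValueError("cannot build groups from an empty junction matrix")
    keys = junctions.introns
    uf = _UnionFind(len(keys))
    by_endpoint: dict[tuple, int] = {}
    for i, key in enumerate(keys):
        for endpoint in (("s", key.chrom, key.strand, key.start),
                         ("e", key.chrom, key.strand, key.end)):
            if endpoint in by_endpoint:
                uf.union(by_endpoint[endpoint], i)
            else:
                by_endpoint[endpoint] = i

    components: dict[int, list[IntronKey]] = {}
    for i, key in enumerate(keys):
        components.setdefault(uf.find(i), []).append(key)
    ordered = sorted(
        (sorted(members, key=lambda k: (k.start, k.end)) for members in components.values()),
        key=lambda members: (members[0].chrom, members[0].start, members[0].end),
    )
    groups: dict[str, list[IntronKey]] = {}
    for members in ordered:
        gid = f"{members[0].chrom}:{members[0].start}:{members[0].strand}"
        if gid in groups:  # same leftmost start on different strands is possible only across strata
            gid = f"{gid}:{members[0].end}"
        groups[gid] = members
    return IntronGroupSet(groups)


def compute_psi(
    junctions: JunctionCountMatrix,
    groups: IntronGroupSet,
    min_group_reads: int = 10,
) -> PsiTensor:
    """PSI(y_i) = y_i / sum_j y_j within each eligible group and sample.

    A group-sample cell is missing (NaN column) when the group's total reads
    in that sample fall below ``min_group_reads``; singleton groups are
    skipped entirely.
    """
    if min_group_reads < 1:
        raise ValueError("min_group_reads must be >= 1")
    index = junctions.intron_index
    members: dict[str, list[IntronKey]] = {}
    psi: dict[str, np.ndarray] = {}
    for gid, group_members in groups.eligible().items():
        try:
            rows = [index[key] for key in group_members]
        except KeyError as exc:
            raise ValueError(f"group {gid} references unknown intron {exc.args[0]}") from None
        sub = junctions.counts[rows, :].astype(float)
        totals = sub.sum(axis=0)
        mat = np.full_like(sub, np.nan)
        ok = totals >= min_group_reads
        if ok.any():
            mat[:, ok] = sub[:, ok] / totals[ok]
        members[gid] = list(group_members)
        psi[gid] = mat
    return PsiTensor(list(junctions.samples), members, psi)


def group_complexity(psi: PsiTensor) -> ComplexityMatrix:
    """s = 1 - (PSI_max - PSI_avg) per group and sample; missing propagates.

    PSI_avg is the mean of the PSI vector, which equals 1/k exactly for a
    complete k-member vector by normalization; computing it as the mean
    keeps the formula faithful even if masking conventions change.
    """
    s_rows = {}
    sizes = {}
    for gid, mat in psi.psi.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            s_rows[gid] = 1.0 - (np.nanmax(mat, axis=0) - np.nanmean(mat, axis=0))
        sizes[gid] = mat.shape[0]
    frame = pd.DataFrame.from_dict(s_rows, orient="index", columns=psi.samples)
    return ComplexityMatrix(frame, sizes)


def aggregate_complexity(
    cm: ComplexityMatrix, min_sample_fraction: float = 0.5
) -> pd.DataFrame:
    """Per-sample aggregate complexity.

    Restricts to groups whose s is defined in at least ``min_sample_fraction``
    of samples, then averages the defined s values per sample.  Returns a
    DataFrame indexed by sample with columns ``aggregate_s`` (NaN when a
    sample has no usable group) and ``n_groups_used``.
    """
    if not (0 < min_sample_fraction <= 1):
        raise ValueError("min_sample_fraction must be in (0, 1]")
    s = cm.s_values
    if s.empty:
        return pd.DataFrame({"aggregate_s": [], "n_groups_used": []})
    defined_frac = s.notna().mean(axis=1)
    usable = s.loc[defined_frac >= min_sample_fraction]
    agg = usable.mean(axis=0, skipna=True)
    n_used = usable.notna().sum(axis=0)
    return pd.DataFrame({"aggregate_s": agg, "n_groups_used": n_used})


def top_variable_groups(
    cm: ComplexityMatrix, n_top: int
) -> tuple[list[str], pd.DataFrame]:
    """Groups ranked by variance of s across samples (most variable first).

    Groups defined in fewer than half the samples are excluded; ties break
    by group id.  Asking for more groups than are eligible returns them all
    with a warning.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    s = cm.s_values
    eligible = s.loc[s.notna().mean(axis=1) >= 0.5]
    variances = eligible.var(axis=1, ddof=1, skipna=True).dropna()
    ranked = sorted(variances.index, key=lambda gid: (-variances[gid], gid))
    if n_top > len(ranked):
        warnings.warn(
            f"requested {n_top} groups but only {len(ranked)} eligible; returning all"
        )
        n_top = len(ranked)
    chosen = ranked[:n_top]
    return chosen, s.loc[chosen]
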