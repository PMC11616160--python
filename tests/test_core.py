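"""Intron parsing, grouping, PSI, and the complexity score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from splicomp.core import (
    IntronKey,
    JunctionCountMatrix,
    IntronGroupSet,
    read_junctions,
    build_groups,
    compute_psi,
    group_complexity,
    aggregate_complexity,
    top_variable_groups,
)
from conftest import random_junction_matrix, grouping_oracle


def _write(path, text):
    path.write_text(text)
    return path


class TestReadJunctions:
    def test_star_coordinates_are_converted_to_half_open(self, tmp_path):
        p = _write(tmp_path / "x.SJ.out.tab", "chr1\t101\t200\t1\t0\t0\t7\t0\t20\n")
        jm = read_junctions(p, dialect="star_sj")
        assert jm.introns == [IntronKey("chr1", 100, 200, "+")]
        assert jm.samples == ["x"]
        assert jm.counts[0, 0] == 7

    def test_star_strand_codes(self, tmp_path):
        p = _write(
            tmp_path / "y.SJ.out.tab",
            "chr1\t11\t20\t0\t0\t0\t1\t0\t9\nchr1\t31\t40\t2\t0\t0\t2\t0\t9\n",
        )
        jm = read_junctions(p, dialect="star_sj")
        assert {k.strand for k in jm.introns} == {".", "-"}

    def test_star_merge_fills_absent_introns_with_zero(self, tmp_path):
        a = _write(tmp_path / "a.SJ.out.tab", "chr1\t101\t200\t1\t0\t0\t5\t0\t9\n")
        b = _write(
            tmp_path / "b.SJ.out.tab",
            "chr1\t101\t200\t1\t0\t0\t2\t0\t9\nchr2\t501\t600\t1\t0\t0\t4\t0\t9\n",
        )
        jm = read_junctions([a, b], dialect="star_sj")
        frame = jm.to_frame()
        assert frame.loc[("chr2", 500, 600, "+"), "a"] == 0
        assert frame.loc[("chr2", 500, 600, "+"), "b"] == 4
        assert frame.loc[("chr1", 100, 200, "+"), "a"] == 5

    def test_duplicate_star_sample_names_rejected(self, tmp_path):
        (tmp_path / "d1").mkdir(); (tmp_path / "d2").mkdir()
        a = _write(tmp_path / "d1" / "s.SJ.out.tab", "chr1\t101\t200\t1\t0\t0\t5\t0\t9\n")
        b = _write(tmp_path / "d2" / "s.SJ.out.tab", "chr1\t101\t200\t1\t0\t0\t5\t0\t9\n")
        with pytest.raises(ValueError, match="sample ids"):
            read_junctions([a, b], dialect="star_sj")

    def test_generic_tsv_roundtrip_values(self, tmp_path):
        p = _write(
            tmp_path / "j.tsv",
            "chrom\tstart\tend\tstrand\ts1\ts2\nchr1\t100\t200\t+\t6\t3\n",
        )
        jm = read_junctions(p, dialect="generic_tsv")
        assert jm.counts.tolist() == [[6, 3]]

    def test_generic_negative_count_errors_with_line_number(self, tmp_path):
        p = _write(
            tmp_path / "j.tsv",
            "chrom\tstart\tend\tstrand\ts1\nchr1\t100\t200\t+\t-3\n",
        )
        with pytest.raises(ValueError, match="line 2"):
            read_junctions(p, dialect="generic_tsv")

    def test_malformed_generic_row_errors_with_line_number(self, tmp_path):
        p = _write(
            tmp_path / "j.tsv",
            "chrom\tstart\tend\tstrand\ts1\nchr1\t100\t200\t+\n",
        )
        with pytest.raises(ValueError, match="line 2"):
            read_junctions(p, dialect="generic_tsv")


class TestBuildGroups:
    def test_chained_endpoints_form_one_group(self):
        a = IntronKey("chr1", 100, 200, "+")
        b = IntronKey("chr1", 100, 300, "+")
        c = IntronKey("chr1", 250, 300, "+")
        jm = JunctionCountMatrix([a, b, c], ["s"], np.ones((3, 1), dtype=int))
        gs = build_groups(jm)
        assert len(gs.groups) == 1
        assert set(next(iter(gs.groups.values()))) == {a, b, c}

    def test_strand_stratification_separates_identical_coordinates(self):
        a = IntronKey("chr1", 100, 200, "+")
        b = IntronKey("chr1", 100, 200, "-")
        jm = JunctionCountMatrix([a, b], ["s"], np.ones((2, 1), dtype=int))
        assert len(build_groups(jm).groups) == 2

    def test_disjoint_introns_stay_singletons(self):
        a = IntronKey("chr1", 100, 200, "+")
        b = IntronKey("chr1", 300, 400, "+")
        jm = JunctionCountMatrix([a, b], ["s"], np.ones((2, 1), dtype=int))
        gs = build_groups(jm)
        assert len(gs.groups) == 2
        assert gs.eligible() == {}

    def test_empty_matrix_rejected(self):
        jm = JunctionCountMatrix([], [], np.zeros((0, 0), dtype=int))
        with pytest.raises(ValueError):
            build_groups(jm)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 60))
    def test_grouping_matches_transitive_closure_oracle(self, seed, n_introns):
        rng = np.random.default_rng(seed)
        jm = random_junction_matrix(rng, n_introns)
        got = {frozenset(m) for m in build_groups(jm).groups.values()}
        assert got == grouping_oracle(jm.introns)


class TestPsi:
    def test_printed_formula(self, three_intron_matrix):
        psi = compute_psi(three_intron_matrix, build_groups(three_intron_matrix), 10)
        (mat,) = psi.psi.values()
        assert mat[:, 0] == pytest.approx([0.6, 0.3, 0.1])

    def test_below_threshold_is_missing(self, three_intron_matrix):
        psi = compute_psi(three_intron_matrix, build_groups(three_intron_matrix), 10)
        (mat,) = psi.psi.values()
        # sample b has 12 reads all on one intron: defined, fully dominated
        assert mat[:, 1] == pytest.approx([0.0, 0.0, 1.0])
        psi13 = compute_psi(three_intron_matrix, build_groups(three_intron_matrix), 13)
        assert np.isnan(next(iter(psi13.psi.values()))[:, 1]).all()

    def test_threshold_boundary(self):
        introns = [IntronKey("chr1", 0, 10, "+"), IntronKey("chr1", 0, 20, "+"),
                   IntronKey("chr1", 5, 20, "+")]
        jm = JunctionCountMatrix(introns, ["s"], np.array([[7], [2], [1]]))
        gs = build_groups(jm)
        hi = next(iter(compute_psi(jm, gs, 11).psi.values()))
        assert np.isnan(hi).all()
        lo = next(iter(compute_psi(jm, gs, 10).psi.values()))
        assert lo[:, 0] == pytest.approx([0.7, 0.2, 0.1])

    def test_unknown_intron_in_group_errors(self, three_intron_matrix):
        bogus = IntronGroupSet({"g": [IntronKey("chrZ", 0, 5, "+"),
                                      IntronKey("chrZ", 0, 9, "+")]})
        with pytest.raises(ValueError, match="unknown intron"):
            compute_psi(three_intron_matrix, bogus, 1)

    def test_defined_psi_vectors_sum_to_one(self, small_cohort):
        psi = compute_psi(small_cohort.junction_counts, small_cohort.truth_groups, 10)
        for mat in psi.psi.values():
            sums = mat.sum(axis=0)
            ok = ~np.isnan(sums)
            assert np.allclose(sums[ok], 1.0, atol=1e-9)
            assert (mat[:, ok] >= 0).all()


class TestComplexity:
    def test_uniform_psi_scores_one(self):
        introns = [IntronKey("chr1", 0, e, "+") for e in (10, 20, 30)]
        jm = JunctionCountMatrix(introns, ["s"], np.array([[4], [4], [4]]))
        cm = group_complexity(compute_psi(jm, build_groups(jm), 1))
        assert cm.s_values.iloc[0, 0] == pytest.approx(1.0)

    def test_fully_dominated_group_scores_one_over_k(self):
        introns = [IntronKey("chr1", 0, e, "+") for e in (10, 20, 30)]
        jm = JunctionCountMatrix(introns, ["s"], np.array([[12], [0], [0]]))
        cm = group_complexity(compute_psi(jm, build_groups(jm), 1))
        assert cm.s_values.iloc[0, 0] == pytest.approx(1 / 3)

    def test_arithmetic_example(self):
        # s = 1 - (0.6 - 1/3) = 0.73333...
        introns = [IntronKey("chr1", 0, e, "+") for e in (10, 20, 30)]
        jm = JunctionCountMatrix(introns, ["s"], np.array([[6], [3], [1]]))
        cm = group_complexity(compute_psi(jm, build_groups(jm), 1))
        psi = np.array([0.6, 0.3, 0.1])
        assert cm.s_values.iloc[0, 0] == pytest.approx(1 - (psi.max() - psi.mean()))

    def test_missing_propagates(self, three_intron_matrix):
        cm = group_complexity(compute_psi(three_intron_matrix, build_groups(three_intron_matrix), 13))
        assert np.isnan(cm.s_values.iloc[0, 1])

    def test_permuting_samples_permutes_outputs(self, small_cohort):
        jm = small_cohort.junction_counts
        perm = list(reversed(jm.samples))
        jm2 = jm.subset_samples(perm)
        cm1 = group_complexity(compute_psi(jm, small_cohort.truth_groups, 10))
        cm2 = group_complexity(compute_psi(jm2, small_cohort.truth_groups, 10))
        pd.testing.assert_frame_equal(cm1.s_values[perm], cm2.s_values)


class TestAggregate:
    def _cm(self, values, samples=None):
        from splicomp.core import ComplexityMatrix

        frame = pd.DataFrame(values, columns=samples or [f"s{i}" for i in range(len(values[0]))])
        frame.index = [f"g{i}" for i in range(len(values))]
        return ComplexityMatrix(frame, {g: 3 for g in frame.index})

    def test_mean_over_groups(self):
        cm = self._cm([[0.4, 0.4], [0.6, 0.6], [0.8, 0.8]])
        agg = aggregate_complexity(cm, 0.5)
        assert agg["aggregate_s"].tolist() == pytest.approx([0.6, 0.6])
        assert agg["n_groups_used"].tolist() == [3, 3]

    def test_single_usable_group_passes_through(self):
        cm = self._cm([[0.7, 0.5], [np.nan, np.nan]])
        agg = aggregate_complexity(cm, 0.5)
        assert agg["aggregate_s"].tolist() == pytest.approx([0.7, 0.5])

    def test_sparse_groups_excluded_by_sample_fraction(self):
        cm = self._cm([[0.9, np.nan, np.nan, np.nan], [0.5, 0.5, 0.5, 0.5]])
        agg = aggregate_complexity(cm, 0.5)
        # first group defined in 25% of samples -> dropped
        assert agg["aggregate_s"].tolist() == pytest.approx([0.5] * 4)

    def test_sample_with_no_usable_groups_is_missing(self):
        cm = self._cm([[0.5, np.nan], [0.7, np.nan]])
        agg = aggregate_complexity(cm, 0.5)
        assert np.isnan(agg["aggregate_s"].iloc[1])


class TestTopVariableGroups:
    def test_higher_variance_group_wins(self):
        cm = TestAggregate()._cm([[0.5, 0.5, 0.5], [0.2, 0.5, 0.9]])
        ids, sub = top_variable_groups(cm, 1)
        assert ids == ["g1"]
        assert list(sub.index) == ["g1"]

    def test_all_missing_group_excluded_and_overask_warns(self):
        cm = TestAggregate()._cm([[0.2, 0.9, 0.4], [np.nan, np.nan, np.nan]])
        with pytest.warns(UserWarning):
            ids, _ = top_variable_groups(cm, 5)
        assert ids == ["g0"]


@pytest.mark.parametrize("k", [2, 3, 4])
def test_s_range_and_extremes_enumerated(k):
    """s in [1/k, 1]; s=1 iff uniform PSI; s=1/k iff one intron has all reads."""
    from itertools import product

    for counts in product(range(13), repeat=k):
        total = sum(counts)
        if total == 0 or total > 12:
            continue
        psi = np.array(counts) / total
        s = 1 - (psi.max() - psi.mean())
        assert 1 / k - 1e-12 <= s <= 1 + 1e-12
        assert (abs(s - 1) < 1e-12) == bool(np.allclose(psi, 1 / k))
        assert (abs(s - 1 / k) < 1e-12) == bool((np.sort(counts)[:-1] == 0).all())
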