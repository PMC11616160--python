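"""GMT parsing and the competitive Wilcoxon rank-sum gene-set test."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from splicomp.genesets import (
    GeneSetCollection,
    read_gmt,
    report_table,
    wilcoxon_gene_set_test,
    write_gmt,
)


def _stats(values):
    return pd.Series(values, index=[f"g{i}" for i in range(len(values))], dtype=float)


def _collection(**sets):
    return GeneSetCollection({k: ("", list(v)) for k, v in sets.items()}, [])


def enumeration_oracle(values, member_idx, alternative="two_sided"):
    """Exhaustive rank-sum null over all same-size subsets of the universe."""
    ranks = rankdata(values)
    m = len(member_idx)
    obs = ranks[list(member_idx)].sum()
    sums = [sum(ranks[list(c)]) for c in combinations(range(len(values)), m)]
    total = len(sums)
    lower = sum(s <= obs + 1e-9 for s in sums) / total
    upper = sum(s >= obs - 1e-9 for s in sums) / total
    if alternative == "up":
        return upper
    if alternative == "down":
        return lower
    return min(1.0, 2.0 * min(lower, upper))


class TestReadGmt:
    def test_roundtrip(self, tmp_path):
        coll = _collection(SET_A=["g1", "g2", "g3"], SET_B=["g4", "g5"])
        write_gmt(coll, tmp_path / "x.gmt")
        back = read_gmt(tmp_path / "x.gmt")
        assert back.sets == coll.sets

    def test_duplicate_genes_collapsed_and_small_sets_flagged(self, tmp_path):
        (tmp_path / "x.gmt").write_text("S1\tdesc\tg1\tg1\tg2\nTINY\tdesc\tg9\n")
        coll = read_gmt(tmp_path / "x.gmt")
        assert coll.members("S1") == ["g1", "g2"]
        assert coll.flagged_small == ["TINY"]

    def test_malformed_row_errors_with_line_number(self, tmp_path):
        (tmp_path / "x.gmt").write_text("S1\tdesc\tg1\nBAD_ROW\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(tmp_path / "x.gmt")

    def test_empty_file_warns(self, tmp_path):
        (tmp_path / "x.gmt").write_text("")
        with pytest.warns(UserWarning, match="empty"):
            coll = read_gmt(tmp_path / "x.gmt")
        assert len(coll) == 0


class TestWilcoxonGeneSetTest:
    def test_top_members_reach_minimal_exact_p(self):
        """Set = top m of N distinct stats: p equals the enumeration value."""
        values = np.arange(20, dtype=float)
        stats = _stats(values)
        members = [f"g{i}" for i in range(15, 20)]
        res = wilcoxon_gene_set_test(stats, _collection(TOP=members), min_set_size=5)
        oracle = enumeration_oracle(values, range(15, 20))
        assert res[0].p == pytest.approx(oracle)
        assert res[0].p == pytest.approx(2 / comb(20, 5))
        assert res[0].direction == "Up"
        assert res[0].method == "exact"

    @pytest.mark.parametrize("alternative", ["two_sided", "up", "down"])
    def test_exact_p_matches_enumeration_with_ties(self, alternative):
        rng = np.random.default_rng(11)
        values = rng.integers(0, 6, size=12).astype(float)  # ties guaranteed
        member_idx = [0, 3, 5, 7, 9]
        stats = _stats(values)
        coll = _collection(S=[f"g{i}" for i in member_idx])
        res = wilcoxon_gene_set_test(stats, coll, min_set_size=5, alternative=alternative)
        assert res[0].p == pytest.approx(
            enumeration_oracle(values, member_idx, alternative)
        )

    def test_sign_flip_swaps_direction_keeps_two_sided_p(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=40)
        members = [f"g{i}" for i in rng.choice(40, 8, replace=False)]
        r1 = wilcoxon_gene_set_test(_stats(values), _collection(S=members))
        r2 = wilcoxon_gene_set_test(_stats(-values), _collection(S=members))
        assert r1[0].p == pytest.approx(r2[0].p, rel=1e-9)
        assert {r1[0].direction, r2[0].direction} == {"Up", "Down"}

    def test_normal_approximation_tracks_scipy_mannwhitney(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=300)
        members = [f"g{i}" for i in rng.choice(300, 30, replace=False)]
        res = wilcoxon_gene_set_test(_stats(values), _collection(S=members))
        member_vals = values[[int(g[1:]) for g in members]]
        rest = np.delete(values, [int(g[1:]) for g in members])
        ref = mannwhitneyu(member_vals, rest, alternative="two-sided",
                           use_continuity=True).pvalue
        assert res[0].p == pytest.approx(ref, abs=1e-6)
        assert res[0].method == "normal"

    def test_exact_and_normal_agree_within_two_percent(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            values = rng.normal(size=50)
            member_idx = rng.choice(50, 10, replace=False)
            ranks = rankdata(values)
            from splicomp.genesets import _exact_ranksum_tails, _normal_tails

            mask = np.zeros(50, dtype=bool)
            mask[member_idx] = True
            lo_e, up_e = _exact_ranksum_tails(np.round(2 * ranks).astype(int), mask)
            lo_n, up_n, _ = _normal_tails(ranks, mask)
            assert abs(min(1, 2 * min(lo_e, up_e)) - min(1, 2 * min(lo_n, up_n))) < 0.02

    def test_monotone_contamination_never_raises_up_p(self):
        """Swapping a member for the top-ranked gene cannot weaken Up evidence."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            values = rng.normal(size=30)
            top = int(np.argmax(values))
            member_idx = rng.choice([i for i in range(30) if i != top], 6, replace=False)
            coll = _collection(S=[f"g{i}" for i in member_idx])
            p_before = wilcoxon_gene_set_test(_stats(values), coll, alternative="up")[0].p
            swapped = list(member_idx[:-1]) + [top]
            coll2 = _collection(S=[f"g{i}" for i in swapped])
            p_after = wilcoxon_gene_set_test(_stats(values), coll2, alternative="up")[0].p
            assert p_after <= p_before + 1e-12

    def test_whole_universe_set_rejected_and_small_set_skipped(self):
        stats = _stats(np.arange(8, dtype=float))
        with pytest.raises(ValueError, match="whole"):
            wilcoxon_gene_set_test(stats, _collection(ALL=list(stats.index)), min_set_size=2)
        with pytest.warns(UserWarning, match="skipped"):
            out = wilcoxon_gene_set_test(stats, _collection(TINY=["g0"]), min_set_size=5)
        assert out == []


class TestReportTable:
    def _results(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=60)
        sets = {f"S{i}": [f"g{j}" for j in rng.choice(60, 8, replace=False)]
                for i in range(6)}
        return wilcoxon_gene_set_test(_stats(values), _collection(**sets))

    def test_sorted_with_nondecreasing_fdr_and_joined_genes(self, tmp_path):
        results = self._results()
        frame = report_table(results, path=tmp_path / "t.tsv")
        assert (frame["fdr"].diff().dropna() >= -1e-12).all()
        assert all(";" in g or g for g in frame["genes"])
        again = report_table(results)
        pd.testing.assert_frame_equal(frame, again)

    def test_top_n_larger_than_results_returns_all(self):
        results = self._results()
        assert len(report_table(results, top_n=100)) == len(results)

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            report_table([])
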