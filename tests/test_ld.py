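"""LD statistics, |D'| confidence bounds and core-region detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan.ld import (CoreRegion, STRONG_LD, STRONG_RECOMB, INCONCLUSIVE,
                          LDStats, TwoLocusCounts, classify_pair,
                          detect_core_regions, dprime_ci, ld_stats,
                          summarize_core_regions, two_locus_counts,
                          _pair_class_codes)

from conftest import make_panel
from oracles import blocks_oracle, dprime_ci_oracle, ld_oracle, pair_counts_oracle

counts_strategy = st.tuples(
    st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
).filter(lambda t: sum(t) >= 4)


class TestTwoLocusCounts:
    def test_identical_columns(self):
        panel = make_panel(np.column_stack([[0, 0, 1, 1], [0, 0, 1, 1]]))
        c = two_locus_counts(panel, 0, 1)
        assert (c.n00, c.n01, c.n10, c.n11) == (2, 0, 0, 2)

    def test_orthogonal_columns(self):
        panel = make_panel(np.column_stack([[0, 1, 0, 1], [0, 0, 1, 1]]))
        c = two_locus_counts(panel, 0, 1)
        assert (c.n00, c.n01, c.n10, c.n11) == (1, 1, 1, 1)

    def test_matches_row_loop_oracle(self):
        rng = np.random.default_rng(5)
        panel = make_panel(rng.integers(0, 2, size=(20, 4)).astype(np.uint8))
        for i, j in [(0, 1), (1, 3), (2, 0)]:
            c = two_locus_counts(panel, i, j)
            o = pair_counts_oracle(panel.haplotypes[:, i], panel.haplotypes[:, j])
            assert (c.n00, c.n01, c.n10, c.n11) == (o["00"], o["01"], o["10"], o["11"])

    def test_out_of_range(self):
        panel = make_panel(np.zeros((4, 2), dtype=np.uint8))
        with pytest.raises(IndexError):
            two_locus_counts(panel, 0, 5)


class TestLDStats:
    def test_perfect_ld(self):
        s = ld_stats(TwoLocusCounts(5, 0, 0, 5))
        assert s.Dprime == pytest.approx(1.0) and s.r2 == pytest.approx(1.0)

    def test_independence(self):
        s = ld_stats(TwoLocusCounts(25, 25, 25, 25))
        assert s.D == 0.0 and s.Dprime == 0.0 and s.r2 == 0.0

    def test_r2_equals_squared_correlation(self):
        # n00=4, n01=1, n10=1, n11=4 as explicit 0/1 vectors
        a = np.array([0] * 5 + [1] * 5)
        b = np.array([0] * 4 + [1] + [0] + [1] * 4)
        s = ld_stats(TwoLocusCounts(4, 1, 1, 4))
        assert s.r2 == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2, abs=1e-12)

    def test_monomorphic_is_uninformative(self):
        assert ld_stats(TwoLocusCounts(10, 0, 10, 0)) is None

    @settings(max_examples=200, deadline=None)
    @given(counts_strategy)
    def test_matches_frequency_oracle(self, counts):
        s = ld_stats(TwoLocusCounts(*counts))
        o = ld_oracle(*counts)
        if o is None:
            assert s is None
            return
        assert s.D == pytest.approx(o[0], abs=1e-12)
        assert s.Dprime == pytest.approx(min(o[1], 1.0), abs=1e-12)
        assert s.r2 == pytest.approx(min(o[2], 1.0), abs=1e-12)
        assert 0 <= s.Dprime <= 1 and 0 <= s.r2 <= 1


class TestDprimeCI:
    def test_strong_association_clears_block_thresholds(self):
        lo, hi = dprime_ci(TwoLocusCounts(50, 0, 0, 50))
        assert lo >= 0.70 and hi >= 0.98

    def test_independence_low_bound_near_zero(self):
        lo, hi = dprime_ci(TwoLocusCounts(25, 25, 25, 25))
        assert lo < 0.70

    @settings(max_examples=100, deadline=None)
    @given(counts_strategy)
    def test_bounds_ordered_in_unit_interval(self, counts):
        res = dprime_ci(TwoLocusCounts(*counts))
        if res is None:
            return
        lo, hi = res
        assert 0.0 <= lo <= hi <= 1.0

    @settings(max_examples=60, deadline=None)
    @given(counts_strategy)
    def test_matches_independent_grid_oracle(self, counts):
        res = dprime_ci(TwoLocusCounts(*counts))
        oracle = dprime_ci_oracle(*counts)
        if oracle is None:
            assert res is None
            return
        assert res == pytest.approx(oracle, abs=1e-9)

    def test_ci_narrows_with_sample_size(self):
        # same underlying frequencies, growing n: width non-increasing on
        # average over replicates
        rng = np.random.default_rng(3)
        probs = [0.4, 0.1, 0.1, 0.4]
        widths = []
        for n in (20, 80, 320):
            w = []
            for _ in range(30):
                c = rng.multinomial(n, probs)
                res = dprime_ci(TwoLocusCounts(*c))
                if res:
                    w.append(res[1] - res[0])
            widths.append(np.mean(w))
        assert widths[0] > widths[1] > widths[2]


class TestClassifyPair:
    @pytest.mark.parametrize("ci, label", [
        ((0.80, 0.99), STRONG_LD),
        ((0.10, 0.60), STRONG_RECOMB),
        ((0.50, 0.95), INCONCLUSIVE),
    ])
    def test_rule(self, ci, label):
        stats = LDStats(D=0.1, Dprime=0.5, r2=0.2, ci_low=ci[0], ci_high=ci[1])
        assert classify_pair(stats) == label

    def test_uninformative(self):
        assert classify_pair(None) == "uninformative"


def _oracle_regions(panel, **kw):
    """Exhaustive-interval oracle fed by the same pair classifications."""
    pos = panel.markers["pos"].to_numpy()
    codes = _pair_class_codes(panel.haplotypes, pos.astype(np.int64),
                              kw.get("max_pair_span_bp", 2_500_000),
                              0.70, 0.98, 0.90, 0.90, 101)
    m = panel.n_markers
    strong = {(i, j): codes[i, j] == 2 for i in range(m) for j in range(i + 1, m)}
    # conclusive pairs only: strong LD or strong recombination
    inform = {(i, j): codes[i, j] >= 1 for i in range(m) for j in range(i + 1, m)}
    return blocks_oracle(strong, inform, list(pos),
                         max_span=kw.get("max_pair_span_bp", 2_500_000))


class TestDetectCoreRegions:
    def test_three_perfect_markers_one_region(self, perfect_ld_panel):
        regions = detect_core_regions(perfect_ld_panel)
        assert len(regions) == 1
        assert regions[0].n_snps == 3
        assert (regions[0].start_pos, regions[0].end_pos) == (10_000, 30_000)
        assert _oracle_regions(perfect_ld_panel) == [(0, 2)]

    def test_weak_pair_gives_no_region(self):
        rng = np.random.default_rng(8)
        panel = make_panel(rng.integers(0, 2, (100, 2)).astype(np.uint8))
        assert detect_core_regions(panel) == []

    def test_two_separated_triples(self):
        rng = np.random.default_rng(1)
        a = np.array([0] * 50 + [1] * 50, dtype=np.uint8)
        b = rng.permutation(a)
        mid = rng.permutation(a)
        panel = make_panel(np.column_stack([a, a, a, mid, b, b, b]))
        regions = detect_core_regions(panel)
        assert [(r.marker_indices[0], r.marker_indices[-1]) for r in regions] == [
            (0, 2), (4, 6)]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_oracle_on_random_small_panels(self, seed):
        rng = np.random.default_rng(seed)
        h, m = 30, rng.integers(4, 9)
        base = rng.integers(0, 2, h).astype(np.uint8)
        cols = []
        for _ in range(m):
            # mix of correlated and independent columns
            if rng.random() < 0.5:
                col = base.copy()
                flips = rng.random(h) < 0.1
                col[flips] = 1 - col[flips]
            else:
                col = rng.integers(0, 2, h).astype(np.uint8)
            cols.append(col)
        panel = make_panel(np.column_stack(cols))
        got = [(r.marker_indices[0], r.marker_indices[-1])
               for r in detect_core_regions(panel)]
        assert got == _oracle_regions(panel)

    def test_invariant_to_other_chromosome(self, perfect_ld_panel):
        rng = np.random.default_rng(9)
        extra = rng.integers(0, 2, (100, 3)).astype(np.uint8)
        combined = make_panel(
            np.hstack([perfect_ld_panel.haplotypes, extra]),
            positions=[10_000, 20_000, 30_000, 5_000, 6_000, 7_000],
            chroms=["1"] * 3 + ["2"] * 3,
        )
        r1 = detect_core_regions(perfect_ld_panel)
        r2 = [r for r in detect_core_regions(combined) if r.chrom == "1"]
        assert [(r.start_pos, r.end_pos) for r in r1] == \
               [(r.start_pos, r.end_pos) for r in r2]

    def test_regions_never_overlap(self, neutral_panel):
        regions = detect_core_regions(neutral_panel)
        assert len(regions) > 5
        for a, b in zip(regions, regions[1:]):
            assert a.marker_indices[-1] < b.marker_indices[0]

    def test_zero_recombination_gives_one_spanning_block(self):
        from sweepscan.simulate import SweepSimParams, simulate_neutral
        p = SweepSimParams(n_haplotypes=200, pop_size=200,
                           chrom_length_bp=500_000,
                           recomb_rate_per_bp_per_gen=0.0,
                           mutation_rate_per_bp_per_gen=4e-8,
                           n_generations=5)
        panel = simulate_neutral(p, seed=13)
        regions = detect_core_regions(panel, max_pair_span_bp=10_000_000)
        assert regions, "no block found without recombination"
        biggest = max(r.n_snps for r in regions)
        assert biggest >= 0.8 * panel.n_markers

    def test_free_recombination_gives_no_multi_snp_block(self):
        # independent markers: every column drawn independently
        rng = np.random.default_rng(17)
        panel = make_panel(rng.integers(0, 2, (200, 30)).astype(np.uint8))
        assert detect_core_regions(panel) == []


class TestSummarize:
    def region(self, panel, lo, hi):
        pos = panel.markers["pos"]
        return CoreRegion(chrom="1", start_pos=int(pos.iloc[lo]),
                          end_pos=int(pos.iloc[hi]),
                          marker_indices=tuple(range(lo, hi + 1)))

    def test_arithmetic(self):
        panel = make_panel(np.random.default_rng(0).integers(0, 2, (4, 8)).astype(np.uint8),
                           positions=[1000, 11_000, 21_000, 40_000, 50_000,
                                      60_000, 70_000, 100_000])
        regions = [self.region(panel, 0, 1), self.region(panel, 3, 6)]
        # lengths: 10 kb and 30 kb
        df = summarize_core_regions(regions, panel)
        row = df[df["chrom"] == "1"].iloc[0]
        assert row["mean_cr_length_kb"] == pytest.approx(20.0)
        assert row["coverage_cr_kb"] == pytest.approx(40.0)
        assert row["max_cr_length_kb"] == pytest.approx(30.0)
        assert row["cr_snps"] == 6

    def test_zero_regions(self, perfect_ld_panel):
        df = summarize_core_regions([], perfect_ld_panel)
        assert (df["n_cr"] == 0).all() and (df["cr_length_ratio"] == 0).all()

    def test_total_row_adds_up(self, neutral_panel):
        regions = detect_core_regions(neutral_panel)
        df = summarize_core_regions(regions, neutral_panel)
        body = df[df["chrom"] != "total"]
        total = df[df["chrom"] == "total"].iloc[0]
        assert total["n_cr"] == body["n_cr"].sum()
        assert total["coverage_cr_kb"] == pytest.approx(body["coverage_cr_kb"].sum())
        assert total["cr_snps"] == body["cr_snps"].sum()
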