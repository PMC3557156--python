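"""Core haplotypes, EHH decay, pooled-other EHH and the REHH test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan.ehh import (DOWNSTREAM, UPSTREAM, core_haplotypes, ehh_at,
                           ehh_bar_at, ehh_decay, rehh_test)
from sweepscan.ld import CoreRegion

from conftest import make_panel
from oracles import ehh_pairs_oracle


def region_over(panel, lo, hi, chrom="1"):
    pos = panel.markers["pos"]
    return CoreRegion(chrom=chrom, start_pos=int(pos.iloc[lo]),
                      end_pos=int(pos.iloc[hi]),
                      marker_indices=tuple(range(lo, hi + 1)))


class TestCoreHaplotypes:
    def test_single_haplotype(self):
        panel = make_panel(np.tile([0, 1], (4, 1)))
        cores = core_haplotypes(panel, region_over(panel, 0, 1))
        assert len(cores) == 1
        assert cores[0].allele_string == "01"
        assert cores[0].frequency(4) == 1.0

    def test_tally_00_00_01_11(self):
        panel = make_panel([[0, 0], [0, 0], [0, 1], [1, 1]])
        cores = core_haplotypes(panel, region_over(panel, 0, 1))
        assert [(c.allele_string, c.carrier_count) for c in cores] == [
            ("00", 2), ("01", 1), ("11", 1)]

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_frequencies_partition(self, seed):
        rng = np.random.default_rng(seed)
        panel = make_panel(rng.integers(0, 2, (10, 5)).astype(np.uint8))
        cores = core_haplotypes(panel, region_over(panel, 1, 3))
        assert sum(c.carrier_count for c in cores) == 10
        assert sum(c.frequency(10) for c in cores) == pytest.approx(1.0)


def build_extension_panel(extensions, core_col=None):
    """Panel with a 2-marker core (all same string unless given) plus
    explicit extension columns."""
    ext = np.asarray(extensions, dtype=np.uint8)
    h = ext.shape[0]
    if core_col is None:
        core = np.zeros((h, 2), dtype=np.uint8)
    else:
        core = np.asarray(core_col, dtype=np.uint8)
    return make_panel(np.hstack([core, ext]))


class TestEhhAt:
    def test_shared_extension_is_one(self):
        panel = build_extension_panel([[1, 0]] * 4)
        core = core_haplotypes(panel, region_over(panel, 0, 1))[0]
        assert ehh_at(panel, core, DOWNSTREAM, 3) == 1.0

    def test_two_two_split_is_one_third(self):
        panel = build_extension_panel([[0, 0], [0, 0], [1, 1], [1, 1]])
        core = core_haplotypes(panel, region_over(panel, 0, 1))[0]
        assert ehh_at(panel, core, DOWNSTREAM, 3) == pytest.approx(1 / 3)

    def test_all_distinct_is_zero(self):
        panel = build_extension_panel([[0, 0], [0, 1], [1, 0], [1, 1]])
        core = core_haplotypes(panel, region_over(panel, 0, 1))[0]
        assert ehh_at(panel, core, DOWNSTREAM, 3) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exact_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        matrix = rng.integers(0, 2, (12, 8)).astype(np.uint8)
        matrix[:, 2:4] = 0  # common 2-marker core for all rows
        panel = make_panel(matrix)
        core = core_haplotypes(panel, region_over(panel, 2, 3))[0]
        for eval_marker, direction, cols in [
            (6, DOWNSTREAM, slice(4, 7)), (0, UPSTREAM, slice(0, 2)),
        ]:
            got = ehh_at(panel, core, direction, eval_marker)
            rows = matrix[np.asarray(core.carrier_rows)][:, cols]
            assert got == float(ehh_pairs_oracle(rows))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_row_permutation_and_allele_flip(self, seed):
        rng = np.random.default_rng(seed)
        matrix = rng.integers(0, 2, (10, 6)).astype(np.uint8)
        matrix[:, 1:3] = 0
        panel = make_panel(matrix)
        core = core_haplotypes(panel, region_over(panel, 1, 2))[0]
        base = ehh_at(panel, core, DOWNSTREAM, 5)
        # permute rows
        perm = rng.permutation(10)
        panel_p = make_panel(matrix[perm])
        core_p = core_haplotypes(panel_p, region_over(panel_p, 1, 2))[0]
        assert ehh_at(panel_p, core_p, DOWNSTREAM, 5) == base
        # flip alleles at one extension marker
        flipped = matrix.copy()
        flipped[:, 4] = 1 - flipped[:, 4]
        panel_f = make_panel(flipped)
        core_f = core_haplotypes(panel_f, region_over(panel_f, 1, 2))[0]
        assert ehh_at(panel_f, core_f, DOWNSTREAM, 5) == base

    def test_singleton_core_is_undefined(self):
        matrix = np.zeros((4, 4), dtype=np.uint8)
        matrix[0, 0] = 1
        panel = make_panel(matrix)
        core = [c for c in core_haplotypes(panel, region_over(panel, 0, 1))
                if c.carrier_count == 1][0]
        with pytest.raises(ValueError, match="singleton"):
            ehh_at(panel, core, DOWNSTREAM, 3)


class TestEhhBarAt:
    def test_pooled_groups_three_and_two(self):
        # carriers: 2 rows of core "11"; others: 3 + 2 internally identical
        rows = (
            [[1, 1, 0, 0]] * 2       # tested core haplotype
            + [[0, 0, 0, 0]] * 3     # other core A, identical extension
            + [[0, 1, 1, 1]] * 2     # other core B, identical extension
        )
        panel = make_panel(rows)
        cores = core_haplotypes(panel, region_over(panel, 0, 1))
        core = [c for c in cores if c.allele_string == "11"][0]
        # EHH-bar = (C(3,2) + C(2,2)) / C(5,2) = 4/10
        assert ehh_bar_at(panel, core, DOWNSTREAM, 3) == pytest.approx(0.4)

    def test_different_cores_never_homozygous(self):
        # all non-carriers share the extension but differ in the core
        rows = [[1, 1, 0]] * 3 + [[0, 0, 0]] * 2 + [[0, 1, 0]] * 2
        panel = make_panel(rows)
        core = [c for c in core_haplotypes(panel, region_over(panel, 0, 1))
                if c.allele_string == "11"][0]
        # groups 2+2 over core+extension: (1+1)/C(4,2)
        assert ehh_bar_at(panel, core, DOWNSTREAM, 2) == pytest.approx(2 / 6)

    def test_single_other_chromosome_undefined(self):
        rows = [[1, 1, 0]] * 5 + [[0, 0, 0]]
        panel = make_panel(rows)
        core = [c for c in core_haplotypes(panel, region_over(panel, 0, 1))
                if c.carrier_count == 5][0]
        with pytest.raises(ValueError, match="fewer than 2"):
            ehh_bar_at(panel, core, DOWNSTREAM, 2)

    def test_identical_others_give_one(self):
        rows = [[1, 1, 0]] * 3 + [[0, 0, 1]] * 3
        panel = make_panel(rows)
        core = [c for c in core_haplotypes(panel, region_over(panel, 0, 1))
                if c.allele_string == "11"][0]
        assert ehh_bar_at(panel, core, DOWNSTREAM, 2) == 1.0


class TestEhhDecay:
    def test_monotone_and_equals_pointwise(self, neutral_panel):
        from sweepscan.ld import detect_core_regions
        regions = detect_core_regions(neutral_panel)
        region = regions[len(regions) // 2]
        core = core_haplotypes(neutral_panel, region)[0]
        for direction in (UPSTREAM, DOWNSTREAM):
            curve = ehh_decay(neutral_panel, core, direction)
            assert np.all(np.diff(curve.ehh_values) <= 1e-12)
            bar = curve.ehh_bar_values
            assert np.all(np.diff(bar[~np.isnan(bar)]) <= 1e-12)
            # spot-check against independent single-position evaluation
            for k in (0, len(curve.eval_positions) - 1):
                pos = curve.eval_positions[k]
                marker = int(np.flatnonzero(
                    neutral_panel.markers["pos"].to_numpy() == pos)[0])
                assert curve.ehh_values[k] == pytest.approx(
                    ehh_at(neutral_panel, core, direction, marker))

    def test_nested_interval_monotonicity(self):
        rng = np.random.default_rng(3)
        matrix = rng.integers(0, 2, (16, 10)).astype(np.uint8)
        matrix[:, 0:2] = 1
        panel = make_panel(matrix)
        core = core_haplotypes(panel, region_over(panel, 0, 1))[0]
        values = [ehh_at(panel, core, DOWNSTREAM, m) for m in range(2, 10)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestRehhTest:
    def test_arithmetic(self, neutral_panel):
        from sweepscan.ld import detect_core_regions
        region = detect_core_regions(neutral_panel)[0]
        core = core_haplotypes(neutral_panel, region)[0]
        rec = rehh_test(neutral_panel, core, DOWNSTREAM)
        assert rec.rehh == pytest.approx(rec.ehh_t / rec.ehh_bar)
        assert rec.status in ("ok", "truncated_end")

    def test_eval_marker_snaps_to_first_at_distance(self):
        rng = np.random.default_rng(4)
        matrix = rng.integers(0, 2, (20, 6)).astype(np.uint8)
        matrix[:, 0:2] = 0
        matrix[15:, 0] = 1  # leave 5 non-carrier chromosomes
        positions = [1000, 2000, 500_000, 990_000, 1_010_000, 1_500_000]
        panel = make_panel(matrix, positions=positions)
        core = core_haplotypes(panel, region_over(panel, 0, 1))[0]
        rec = rehh_test(panel, core, DOWNSTREAM, target_distance_bp=1_000_000)
        # first marker >= 1 Mb beyond the region end (pos 2000): 1,010,000
        assert rec.eval_pos == 1_010_000
        assert rec.status == "ok"

    def test_truncated_end_flagged(self):
        rng = np.random.default_rng(4)
        matrix = rng.integers(0, 2, (20, 4)).astype(np.uint8)
        matrix[:, 0:2] = 0
        matrix[15:, 0] = 1
        panel = make_panel(matrix, positions=[1000, 2000, 3000, 4000])
        core = core_haplotypes(panel, region_over(panel, 0, 1))[0]
        rec = rehh_test(panel, core, DOWNSTREAM, target_distance_bp=1_000_000)
        assert rec.status in ("truncated_end", "undefined_bar")
        assert rec.eval_pos == 4000

    def test_batch_accounting_two_tests_per_testable_core(self, neutral_panel,
                                                          neutral_scan_result):
        """Tests emitted = testable core haplotypes x 2 directions."""
        from sweepscan.ld import detect_core_regions
        h = neutral_panel.n_haplotypes
        regions = neutral_scan_result.regions
        expected = 0
        for region in regions:
            for c in core_haplotypes(neutral_panel, region):
                if 2 <= c.carrier_count <= h - 2:
                    expected += 2
        assert neutral_scan_result.n_tests_total == expected
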