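"""Sliding windows, windowed mF_ST, percentile outlier calling, merging."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from poolscan.errors import UndefinedResultError, ValidationError
from poolscan.scan import (
    Window,
    call_outliers,
    make_windows,
    merge_outliers,
    window_mfst,
)


def brute_force_windows(length: int, window: int, step: int) -> list[tuple[int, int]]:
    """Independent enumeration of the window rule."""
    out = []
    start = 0
    while start < length:
        out.append((start, min(start + window, length)))
        start += step
    return out


def snp_track(chrom, pos, fst) -> pd.DataFrame:
    return pd.DataFrame({"chrom": chrom, "pos": pos, "fst": fst})


class TestMakeWindows:
    def test_enumerated_default_windows_for_1200kb(self):
        windows = make_windows({"chr1": 1_200_000})
        spans = [(w.start, w.end) for w in windows]
        assert spans == [
            (0, 500_000),
            (250_000, 750_000),
            (500_000, 1_000_000),
            (750_000, 1_200_000),
            (1_000_000, 1_200_000),
        ]

    def test_chromosome_shorter_than_window_truncates(self):
        windows = make_windows({"chr1": 400_000})
        assert [(w.start, w.end) for w in windows] == [(0, 400_000), (250_000, 400_000)]

    def test_step_equal_to_window_tiles_without_overlap(self):
        windows = make_windows({"chr1": 1_000_000}, window_size=250_000, step=250_000)
        spans = [(w.start, w.end) for w in windows]
        assert spans == [(i * 250_000, (i + 1) * 250_000) for i in range(4)]

    @pytest.mark.parametrize("length", [400_000, 1_200_000, 10_000_000])
    def test_matches_brute_force_enumeration(self, length):
        windows = make_windows({"c": length})
        assert [(w.start, w.end) for w in windows] == brute_force_windows(
            length, 500_000, 250_000
        )

    def test_drop_truncated_mode(self):
        windows = make_windows({"chr1": 1_200_000}, keep_truncated=False)
        assert [(w.start, w.end) for w in windows] == [
            (0, 500_000), (250_000, 750_000), (500_000, 1_000_000)
        ]

    def test_validation(self):
        with pytest.raises(ValidationError):
            make_windows({"chr1": 0})
        with pytest.raises(ValidationError):
            make_windows({"chr1": 100}, window_size=10, step=20)
        with pytest.raises(ValidationError):
            make_windows({"chr1": 100}, window_size=0)


class TestWindowMfst:
    def test_mean_and_count(self):
        windows = [Window("chr1", 0, 500_000)]
        track = snp_track("chr1", [10_000, 20_000, 30_000], [0.1, 0.2, 0.3])
        (w,) = window_mfst(windows, track)
        assert w.n_snps == 3
        assert w.mfst == pytest.approx(0.2)

    def test_snp_on_step_boundary_counts_in_both_windows(self):
        windows = make_windows({"chr1": 1_000_000})
        track = snp_track("chr1", [250_000], [0.4])
        filled = window_mfst(windows, track)
        hit = [(w.start, w.end) for w in filled if w.n_snps == 1]
        assert hit == [(0, 500_000), (250_000, 750_000)]

    def test_undefined_fst_excluded_from_count_and_mean(self):
        windows = [Window("chr1", 0, 500_000)]
        track = snp_track("chr1", [10_000, 20_000], [float("nan"), 0.6])
        (w,) = window_mfst(windows, track)
        assert w.n_snps == 1
        assert w.mfst == pytest.approx(0.6)

    def test_window_without_snps_has_no_mfst(self):
        windows = [Window("chr1", 0, 500_000), Window("chr2", 0, 500_000)]
        filled = window_mfst(windows, snp_track("chr1", [1], [0.5]))
        assert filled[1].n_snps == 0
        assert not filled[1].has_mfst

    def test_random_fixture_matches_brute_force_rescan(self):
        rng = np.random.default_rng(5)
        lengths = {f"chr{i}": 2_000_000 for i in range(1, 4)}
        rows = []
        for chrom in lengths:
            pos = np.sort(rng.choice(2_000_000, size=500, replace=False)) + 1
            for p in pos:
                rows.append((chrom, int(p), float(rng.uniform(0, 1))))
        track = pd.DataFrame(rows, columns=["chrom", "pos", "fst"])
        filled = window_mfst(make_windows(lengths), track)
        for w in filled:
            sub = track[(track["chrom"] == w.chrom)
                        & (track["pos"] >= w.start) & (track["pos"] < w.end)]
            assert w.n_snps == len(sub)
            if len(sub):
                assert w.mfst == pytest.approx(sub["fst"].mean(), abs=1e-12)


class TestCallOutliers:
    def make_permutation_windows(self, n=300, n_snps=500):
        rng = np.random.default_rng(42)
        values = rng.permutation(np.arange(1, n + 1)) / n
        return [
            Window("chr1", i * 250_000, i * 250_000 + 500_000, n_snps=n_snps, mfst=v)
            for i, v in enumerate(values)
        ]

    def test_permutation_fixture_threshold_and_retained_set(self):
        windows = self.make_permutation_windows()
        call = call_outliers(windows, percentile=99, min_snps=200)
        # linear-interpolation 99th percentile of {1..300}/300 is 297.01/300
        assert call.threshold == pytest.approx(297.01 / 300, abs=1e-12)
        retained_vals = sorted(round(w.mfst * 300) for w in call.retained)
        assert retained_vals == [298, 299, 300]

    def test_degenerate_distribution_retains_nothing(self):
        windows = [
            Window("chr1", i * 250_000, i * 250_000 + 500_000, n_snps=500, mfst=0.2)
            for i in range(10)
        ]
        call = call_outliers(windows)
        assert call.threshold == pytest.approx(0.2)
        assert call.retained == []

    def test_min_snps_boundary_is_strict(self):
        windows = self.make_permutation_windows()
        # the top window has mfst 300/300; give it exactly 200 SNPs
        top = max(range(len(windows)), key=lambda i: windows[i].mfst)
        windows[top] = Window(
            windows[top].chrom, windows[top].start, windows[top].end,
            n_snps=200, mfst=windows[top].mfst,
        )
        call = call_outliers(windows)
        assert all(round(w.mfst * 300) != 300 for w in call.retained)
        windows[top] = Window(
            windows[top].chrom, windows[top].start, windows[top].end,
            n_snps=201, mfst=windows[top].mfst,
        )
        call = call_outliers(windows)
        assert any(round(w.mfst * 300) == 300 for w in call.retained)

    def test_retained_fraction_bounded_without_snp_rule(self):
        windows = self.make_permutation_windows(n=250)
        call = call_outliers(windows, percentile=99, min_snps=0)
        bound = math.ceil(0.01 * call.n_windows_with_mfst)
        assert len(call.retained) <= bound + 1  # + ties at the threshold

    def test_no_defined_mfst_is_an_error(self):
        with pytest.raises(UndefinedResultError):
            call_outliers([Window("chr1", 0, 500_000)])

    def test_percentile_order_modes_differ_when_low_snp_windows_dominate(self):
        windows = [
            Window("chr1", i * 500_000, (i + 1) * 500_000, n_snps=(10 if i < 90 else 500),
                   mfst=(0.9 if i < 90 else i / 1000))
            for i in range(100)
        ]
        before = call_outliers(windows, min_snps=200, percentile_after_min_snps=False)
        after = call_outliers(windows, min_snps=200, percentile_after_min_snps=True)
        # low-SNP high-mfst windows inflate the threshold only in 'before' mode
        assert before.threshold > after.threshold


class TestMergeOutliers:
    def test_overlapping_windows_merge(self):
        merged = merge_outliers(
            [Window("chr1", 0, 500_000, 300, 0.5), Window("chr1", 250_000, 750_000, 280, 0.6)]
        )
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, 750_000)
        assert merged[0].peak_mfst == pytest.approx(0.6)
        assert merged[0].total_snps == 580

    def test_gap_preserved(self):
        merged = merge_outliers(
            [Window("chr1", 0, 500_000, 300, 0.5), Window("chr1", 750_000, 1_250_000, 300, 0.5)]
        )
        assert len(merged) == 2

    def test_bookended_windows_merge(self):
        merged = merge_outliers(
            [Window("chr1", 0, 500_000, 300, 0.5), Window("chr1", 500_000, 1_000_000, 300, 0.5)]
        )
        assert len(merged) == 1
        assert merged[0].end == 1_000_000

    def test_run_of_overlapping_windows_spans_first_start_to_last_end(self):
        k = 7
        run = [Window("chr1", i * 250_000, i * 250_000 + 500_000, 300, 0.5) for i in range(k)]
        merged = merge_outliers(run)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (0, (k - 1) * 250_000 + 500_000)
        assert len(merged[0].windows) == k

    def test_chromosomes_do_not_merge_and_coverage_is_preserved(self):
        rng = np.random.default_rng(3)
        windows = []
        for chrom in ("chr1", "chr2"):
            for i in sorted(rng.choice(40, size=12, replace=False)):
                windows.append(Window(chrom, i * 250_000, i * 250_000 + 500_000, 300, 0.5))
        merged = merge_outliers(windows)
        assert all(r.chrom in ("chr1", "chr2") for r in merged)
        # identical bp coverage: union of windows == union of regions
        covered_w = set()
        for w in windows:
            covered_w.update(range(w.start // 250_000, w.end // 250_000))
        covered_r = set()
        for r in merged:
            covered_r.update(range(r.start // 250_000, r.end // 250_000))
        assert covered_w == covered_r
        # regions on one chromosome are disjoint
        for chrom in ("chr1", "chr2"):
            spans = sorted((r.start, r.end) for r in merged if r.chrom == chrom)
            assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
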