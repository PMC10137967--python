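"""Variant table I/O, site filtering, frequencies, pool combination."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import make_table
from poolscan.errors import FormatError, UndefinedResultError, ValidationError
from poolscan.simulate import SimConfig, generate_dataset
from poolscan.variant_io import (
    combine_pools,
    compute_frequencies,
    filter_sites,
    fixed_allele_proportion,
    read_variants,
    write_tsv,
    write_vcf,
)


@pytest.fixture
def five_site_table():
    """One triallelic site, one at the quality boundary, one under mean depth,
    two passing sites."""
    rows = [
        ("chr1", 100, "A", "C,G", 500.0),  # triallelic -> removed
        ("chr1", 200, "A", "C", 100.0),    # quality not strictly > 100 -> removed
        ("chr1", 300, "G", "T", 500.0),    # mean depth 39.5 < 40 -> removed
        ("chr1", 400, "T", "A", 100.01),   # boundary: retained
        ("chr1", 500, "C", "G", 500.0),    # retained
    ]
    depths = [
        [(30, 30), (30, 30)],
        [(30, 30), (30, 30)],
        [(20, 19), (20, 20)],  # totals 39 and 40 -> mean 39.5
        [(20, 20), (20, 20)],  # mean exactly 40.0
        [(40, 20), (10, 50)],
    ]
    return make_table(rows, ["P1", "P2"], depths)


class TestFilterSites:
    def test_five_site_fixture_keeps_exactly_the_two_qualifying_sites(self, five_site_table):
        filtered, report = filter_sites(five_site_table)
        assert list(filtered.sites["pos"]) == [400, 500]
        assert report.n_input == 5 and report.n_retained == 2
        assert report.removed_not_biallelic == 1
        assert report.removed_quality == 1
        assert report.removed_depth == 1
        assert (
            report.removed_not_biallelic + report.removed_quality + report.removed_depth
            == report.n_removed
        )

    def test_boundary_semantics(self, five_site_table):
        # quality 100.01 (strict >) with mean depth exactly 40.0 (non-strict >=)
        filtered, _ = filter_sites(five_site_table)
        assert 400 in set(filtered.sites["pos"])
        assert 200 not in set(filtered.sites["pos"])
        assert 300 not in set(filtered.sites["pos"])

    def test_idempotence_on_random_table(self):
        ds = generate_dataset(SimConfig(n_snps=400, low_quality_fraction=0.2, seed=9))
        once, _ = filter_sites(ds.variants)
        twice, report = filter_sites(once)
        assert once.equals(twice)
        assert report.n_removed == 0

    def test_all_filtered_is_valid_empty_result(self, five_site_table):
        filtered, report = filter_sites(five_site_table, min_quality=1e9)
        assert filtered.n_sites == 0
        assert report.n_retained == 0


class TestFrequencies:
    def test_basic_ratios_and_missingness(self):
        table = make_table(
            [("chr1", 1, "A", "C", 500.0), ("chr1", 2, "A", "C", 500.0),
             ("chr1", 3, "A", "C", 500.0)],
            ["P1"],
            [[(30, 10)], [(0, 55)], [(0, 0)]],
        )
        freqs = compute_frequencies(table)
        assert freqs.freq[0, 0] == pytest.approx(0.25)
        assert freqs.freq[1, 0] == pytest.approx(1.0)
        assert np.isnan(freqs.freq[2, 0])  # never 0/0 == 0

    def test_combined_pool_frequency_is_depth_weighted_mean(self):
        ds = generate_dataset(SimConfig(n_snps=300, seed=4))
        combined = combine_pools(ds.variants, ["A1", "A2", "A3"], "A")
        fa = compute_frequencies(combined).pool_frequencies("A")
        f = compute_frequencies(ds.variants)
        member = [f.pool_index(p) for p in ("A1", "A2", "A3")]
        depth = f.total_depth[:, member]
        weighted = np.nansum(f.freq[:, member] * depth, axis=1) / depth.sum(axis=1)
        np.testing.assert_allclose(fa, weighted, rtol=0, atol=1e-12)


class TestCombinePools:
    def test_counts_are_additive(self):
        table = make_table(
            [("chr1", 1, "A", "C", 500.0)], ["X", "Y"], [[(10, 0), (0, 10)]]
        )
        combined = combine_pools(table, ["X", "Y"], "Z")
        assert combined.pools == ["Z"]
        assert combined.ref_depth[0, 0] == 10 and combined.alt_depth[0, 0] == 10
        assert compute_frequencies(combined).freq[0, 0] == pytest.approx(0.5)

    def test_single_member_is_identity_on_counts(self):
        ds = generate_dataset(SimConfig(n_snps=100, seed=6))
        combined = combine_pools(ds.variants, ["B"], "B2")
        j_old = ds.variants.pool_index("B")
        j_new = combined.pool_index("B2")
        assert np.array_equal(combined.ref_depth[:, j_new], ds.variants.ref_depth[:, j_old])
        assert np.array_equal(combined.alt_depth[:, j_new], ds.variants.alt_depth[:, j_old])

    def test_depth_is_conserved(self):
        ds = generate_dataset(SimConfig(n_snps=100, seed=6))
        combined = combine_pools(ds.variants, ["A1", "A2", "A3"], "A")
        assert np.array_equal(
            combined.total_depth.sum(axis=1), ds.variants.total_depth.sum(axis=1)
        )

    def test_unknown_member_rejected(self):
        ds = generate_dataset(SimConfig(n_snps=50, seed=6))
        with pytest.raises(ValidationError):
            combine_pools(ds.variants, ["A1", "nope"], "A")


class TestFixedAlleleProportion:
    def test_counts_exact_zeros_and_ones(self):
        table = make_table(
            [("chr1", i, "A", "C", 500.0) for i in range(1, 5)],
            ["P"],
            [[(10, 0)], [(0, 10)], [(5, 5)], [(7, 3)]],
        )
        freqs = compute_frequencies(table)
        assert fixed_allele_proportion(freqs, "P") == pytest.approx(0.5)

    def test_no_fixed_sites(self):
        table = make_table(
            [("chr1", 1, "A", "C", 500.0)], ["P"], [[(5, 5)]]
        )
        assert fixed_allele_proportion(compute_frequencies(table), "P") == 0.0

    def test_zero_defined_sites_is_an_error(self):
        table = make_table([("chr1", 1, "A", "C", 500.0)], ["P"], [[(0, 0)]])
        with pytest.raises(UndefinedResultError):
            fixed_allele_proportion(compute_frequencies(table), "P")


class TestRoundTrips:
    @pytest.mark.parametrize("fmt", ["vcf", "tsv"])
    def test_write_read_is_identity(self, tmp_path, fmt, demo_dataset):
        table = demo_dataset.variants
        path = tmp_path / f"t.{fmt}"
        (write_vcf if fmt == "vcf" else write_tsv)(table, path)
        back = read_variants(path)
        assert back.pools == table.pools
        assert np.array_equal(back.ref_depth, table.ref_depth)
        assert np.array_equal(back.alt_depth, table.alt_depth)
        assert list(back.sites["pos"]) == list(table.sites["pos"])
        assert list(back.sites["qual"]) == pytest.approx(list(table.sites["qual"]))

    @pytest.mark.parametrize("fmt", ["vcf", "tsv"])
    def test_write_read_write_is_byte_stable(self, tmp_path, fmt, demo_dataset):
        writer = write_vcf if fmt == "vcf" else write_tsv
        p1 = tmp_path / f"a.{fmt}"
        p2 = tmp_path / f"b.{fmt}"
        writer(demo_dataset.variants, p1)
        writer(read_variants(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    @pytest.mark.parametrize("fmt", ["vcf", "tsv"])
    def test_empty_file_reads_as_empty_table(self, tmp_path, fmt):
        path = tmp_path / f"empty.{fmt}"
        path.write_text("")
        table = read_variants(path)
        assert table.n_sites == 0

    def test_three_record_tsv_round_trip(self, tmp_path):
        table = make_table(
            [("chr1", 10, "A", "C", 150.0), ("chr1", 20, "G", "T", 200.5),
             ("chr2", 5, "C", "A", 300.0)],
            ["P1", "P2"],
            [[(10, 5), (8, 2)], [(0, 30), (30, 0)], [(12, 12), (1, 0)]],
        )
        path = tmp_path / "t.tsv"
        write_tsv(table, path)
        back = read_variants(path)
        assert back.n_sites == 3
        assert np.array_equal(back.ref_depth, table.ref_depth)
        assert np.array_equal(back.alt_depth, table.alt_depth)

    def test_vcf_without_ad_field_is_a_format_error(self, tmp_path):
        path = tmp_path / "noad.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\n"
            "chr1\t100\t.\tA\tC\t200\t.\t.\tGT\t0/1\n"
        )
        with pytest.raises(FormatError, match="chr1:100"):
            read_variants(path)

    def test_multiallelic_records_are_retained_on_read(self, tmp_path):
        table = make_table(
            [("chr1", 10, "A", "C,G", 150.0), ("chr1", 20, "G", "T", 200.0)],
            ["P1"],
            [[(10, 5)], [(8, 2)]],
        )
        path = tmp_path / "t.vcf"
        write_vcf(table, path)
        back = read_variants(path)
        assert back.n_sites == 2
        assert back.sites.at[0, "alt"] == "C,G"
        assert not back.is_biallelic_snp()[0]
        assert back.is_biallelic_snp()[1]
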