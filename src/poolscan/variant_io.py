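"""Pool variant tables: reading, writing, filtering, allele frequencies.

The central container is :class:`PoolVariantTable` — per-site, per-pool
ref/alt read depths plus a site quality, i.e. the information a pooled
variant caller leaves behind once reads have been aligned and variants
called.  Two on-disk representations are supported:

* VCF 4.2 with one sample column per DNA pool and allelic depths in the
  per-sample ``AD`` field (read via :mod:`pysam`);
* a flat TSV dialect with columns ``chrom  pos  ref  alt  qual`` followed by
  one ``<pool>_ref  <pool>_alt`` column pair per pool.

Coordinates are 1-based in both file formats and are kept 1-based on the
``pos`` column internally; windowed coordinates used elsewhere in the
package are 0-based half-open (see :mod:`poolscan.scan`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from poolscan.errors import FormatError, UndefinedResultError, ValidationError

SITE_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]

_BASES = frozenset("ACGT")


@dataclass
class PoolVariantTable:
    """Per-site, per-pool read depths for both alleles.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom`` (str), ``pos`` (int, 1-based),
        ``ref`` (str), ``alt`` (str, comma-separated if multi-allelic) and
        ``qual`` (float).  Row order is the site order.
    pools
        Ordered pool names, one per sample column.
    ref_depth, alt_depth
        Integer arrays of shape ``(n_sites, n_pools)``.  For multi-allelic
        records ``alt_depth`` holds the depth of the first alternate allele;
        such records are flagged by :meth:`is_biallelic_snp` and removed by
        :func:`filter_sites`.
    """

    sites: pd.DataFrame
    pools: list[str]
    ref_depth: np.ndarray
    alt_depth: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.ref_depth = np.asarray(self.ref_depth, dtype=np.int64).reshape(
            len(self.sites), len(self.pools)
        )
        self.alt_depth = np.asarray(self.alt_depth, dtype=np.int64).reshape(
            len(self.sites), len(self.pools)
        )
        if len(self.pools) == 0 and len(self.sites) > 0:
            raise ValidationError("pool list must be non-empty")
        if len(set(self.pools)) != len(self.pools):
            raise ValidationError("pool names must be unique")
        if (self.ref_depth < 0).any() or (self.alt_depth < 0).any():
            raise ValidationError("read depths must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def total_depth(self) -> np.ndarray:
        """Per-site x per-pool total read depth."""
        return self.ref_depth + self.alt_depth

    def is_biallelic_snp(self) -> np.ndarray:
        """Boolean mask of sites that are biallelic single-base substitutions."""
        ref = self.sites["ref"].to_numpy(dtype=object)
        alt = self.sites["alt"].to_numpy(dtype=object)
        mask = np.fromiter(
            (
                isinstance(r, str)
                and isinstance(a, str)
                and len(r) == 1
                and len(a) == 1
                and r in _BASES
                and a in _BASES
                and r != a
                for r, a in zip(ref, alt)
            ),
            dtype=bool,
            count=len(ref),
        )
        return mask

    def pool_index(self, name: str) -> int:
        try:
            return self.pools.index(name)
        except ValueError:
            raise ValidationError(f"unknown pool name: {name!r}") from None

    def subset_sites(self, mask: np.ndarray) -> "PoolVariantTable":
        """Return a new table restricted to sites where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        return PoolVariantTable(
            sites=self.sites.loc[mask].reset_index(drop=True),
            pools=list(self.pools),
            ref_depth=self.ref_depth[mask],
            alt_depth=self.alt_depth[mask],
        )

    def equals(self, other: "PoolVariantTable") -> bool:
        return (
            self.pools == other.pools
            and self.sites.reset_index(drop=True).equals(
                other.sites.reset_index(drop=True)
            )
            and np.array_equal(self.ref_depth, other.ref_depth)
            and np.array_equal(self.alt_depth, other.alt_depth)
        )


@dataclass
class FrequencyMatrix:
    """Alternate-allele frequencies per site and pool.

    ``freq`` holds p = alt / (ref + alt); entries with zero total depth are
    NaN (missing), never coerced to 0.  ``q = 1 - p`` throughout the package.
    """

    sites: pd.DataFrame
    pools: list[str]
    freq: np.ndarray
    total_depth: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def pool_index(self, name: str) -> int:
        try:
            return self.pools.index(name)
        except ValueError:
            raise ValidationError(f"unknown pool name: {name!r}") from None

    def pool_frequencies(self, name: str) -> np.ndarray:
        return self.freq[:, self.pool_index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = self.sites[["chrom", "pos"]].copy()
        for j, pool in enumerate(self.pools):
            df[pool] = self.freq[:, j]
            df[f"{pool}_depth"] = self.total_depth[:, j]
        return df


@dataclass
class FilterReport:
    """Bookkeeping for :func:`filter_sites`.

    Each removed site is attributed to the first criterion it fails, in the
    order: not a biallelic SNP, quality, mean depth; the three counts
    therefore sum to ``n_removed``.
    """

    n_input: int
    n_retained: int
    removed_not_biallelic: int
    removed_quality: int
    removed_depth: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".vcf"}:
        return "vcf"
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    raise ValidationError(
        f"cannot infer variant format from {path!r}; pass format='vcf' or 'tsv'"
    )


def read_variants(path: str | Path, format: str | None = None) -> PoolVariantTable:
    """Read a pool variant table from VCF or the TSV dialect.

    Input order is preserved; multi-allelic records are retained (they are
    removed later by :func:`filter_sites`).
    """
    fmt = format or _infer_format(path)
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValidationError(f"unknown variant format {fmt!r}")


def _empty_table() -> PoolVariantTable:
    return PoolVariantTable(
        sites=pd.DataFrame(columns=SITE_COLUMNS),
        pools=[],
        ref_depth=np.empty((0, 0), dtype=np.int64),
        alt_depth=np.empty((0, 0), dtype=np.int64),
    )


def _read_vcf(path: str | Path) -> PoolVariantTable:
    path = Path(path)
    if path.stat().st_size == 0:
        return _empty_table()
    with pysam.VariantFile(str(path)) as vcf:
        pools = list(vcf.header.samples)
        if not pools:
            raise FormatError(f"{path}: VCF has no sample (pool) columns")
        rows = []
        ref_rows: list[list[int]] = []
        alt_rows: list[list[int]] = []
        for rec in vcf:
            alts = rec.alts or ()
            site_id = f"{rec.chrom}:{rec.pos}"
            refs_pool = []
            alts_pool = []
            for pool in pools:
                sample = rec.samples[pool]
                ad = sample.get("AD")
                if ad is None or ad[0] is None:
                    raise FormatError(
                        f"{path}: missing AD (allelic depth) for pool {pool!r} at {site_id}"
                    )
                refs_pool.append(int(ad[0]))
                alts_pool.append(int(ad[1]) if len(ad) > 1 and ad[1] is not None else 0)
            rows.append(
                (
                    rec.chrom,
                    int(rec.pos),
                    rec.ref,
                    ",".join(alts) if alts else ".",
                    float(rec.qual) if rec.qual is not None else float("nan"),
                )
            )
            ref_rows.append(refs_pool)
            alt_rows.append(alts_pool)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    n = len(sites)
    return PoolVariantTable(
        sites=sites,
        pools=pools,
        ref_depth=np.array(ref_rows, dtype=np.int64).reshape(n, len(pools)),
        alt_depth=np.array(alt_rows, dtype=np.int64).reshape(n, len(pools)),
    )


def _read_tsv(path: str | Path) -> PoolVariantTable:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return _empty_table()
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: TSV missing required columns {missing}")
    pool_cols = [c for c in df.columns if c not in SITE_COLUMNS]
    pools: list[str] = []
    for col in pool_cols:
        if col.endswith("_ref"):
            name = col[: -len("_ref")]
            if f"{name}_alt" not in df.columns:
                raise FormatError(f"{path}: column {col} has no matching {name}_alt")
            pools.append(name)
        elif not col.endswith("_alt"):
            raise FormatError(f"{path}: unexpected column {col!r}")
    if not pools:
        raise FormatError(f"{path}: no <pool>_ref/<pool>_alt column pairs found")
    try:
        pos = df["pos"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: malformed coordinates in 'pos' column") from exc
    sites = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "pos": pos,
            "ref": df["ref"].astype(str),
            "alt": df["alt"].astype(str),
            "qual": df["qual"].astype(float),
        }
    )
    n = len(sites)
    ref_depth = df[[f"{p}_ref" for p in pools]].to_numpy(dtype=np.int64).reshape(n, len(pools))
    alt_depth = df[[f"{p}_alt" for p in pools]].to_numpy(dtype=np.int64).reshape(n, len(pools))
    return PoolVariantTable(sites=sites, pools=pools, ref_depth=ref_depth, alt_depth=alt_depth)


def _format_qual(q: float) -> str:
    if np.isnan(q):
        return "."
    if float(q).is_integer():
        return str(int(q))
    return format(float(q), ".6g")


def write_vcf(table: PoolVariantTable, path: str | Path) -> None:
    """Write the table as minimal VCF 4.2 with per-sample AD fields.

    The writer emits a canonical byte layout so that write -> read -> write
    round-trips are byte-stable.
    """
    chroms = list(dict.fromkeys(table.sites["chrom"]))
    lines = ["##fileformat=VCFv4.2"]
    # contig lengths: max observed position rounded up; enough for htslib to parse
    for chrom in chroms:
        max_pos = int(table.sites.loc[table.sites["chrom"] == chrom, "pos"].max())
        lines.append(f"##contig=<ID={chrom},length={max_pos + 1}>")
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
        '"Allelic depths for the ref and alt alleles in the order listed">'
    )
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(table.pools)
    lines.append("\t".join(header))
    sites = table.sites
    for i in range(table.n_sites):
        row = [
            str(sites.at[i, "chrom"]),
            str(int(sites.at[i, "pos"])),
            ".",
            str(sites.at[i, "ref"]),
            str(sites.at[i, "alt"]),
            _format_qual(float(sites.at[i, "qual"])),
            ".",
            ".",
            "AD",
        ]
        for j in range(len(table.pools)):
            row.append(f"{table.ref_depth[i, j]},{table.alt_depth[i, j]}")
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_tsv(table: PoolVariantTable, path: str | Path) -> None:
    """Write the table in the flat TSV dialect."""
    cols = list(SITE_COLUMNS)
    df = table.sites[cols].copy()
    df["qual"] = [_format_qual(q) for q in df["qual"].astype(float)]
    for j, pool in enumerate(table.pools):
        df[f"{pool}_ref"] = table.ref_depth[:, j]
        df[f"{pool}_alt"] = table.alt_depth[:, j]
    df.to_csv(path, sep="\t", index=False)


def write_frequencies(freqs: FrequencyMatrix, path: str | Path) -> None:
    freqs.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def filter_sites(
    table: PoolVariantTable,
    min_quality: float = 100.0,
    min_mean_depth: float = 40.0,
) -> tuple[PoolVariantTable, FilterReport]:
    """Apply the study's site filters.

    A site is retained iff it is a biallelic SNP, its quality is strictly
    greater than ``min_quality``, and the arithmetic mean over pools of its
    per-pool total depth is at least ``min_mean_depth`` (non-strict).  Site
    order is preserved and the report attributes each removed site to the
    first criterion it fails.
    """
    biallelic = table.is_biallelic_snp()
    quality_ok = table.sites["qual"].to_numpy(dtype=float) > min_quality
    mean_depth = table.total_depth.mean(axis=1) if table.n_sites else np.empty(0)
    depth_ok = mean_depth >= min_mean_depth
    keep = biallelic & quality_ok & depth_ok
    report = FilterReport(
        n_input=table.n_sites,
        n_retained=int(keep.sum()),
        removed_not_biallelic=int((~biallelic).sum()),
        removed_quality=int((biallelic & ~quality_ok).sum()),
        removed_depth=int((biallelic & quality_ok & ~depth_ok).sum()),
    )
    return table.subset_sites(keep), report


def compute_frequencies(table: PoolVariantTable) -> FrequencyMatrix:
    """Alternate-allele frequency p = alt / (ref + alt) per site and pool.

    Zero-depth entries are flagged missing (NaN) rather than treated as 0.
    """
    depth = table.total_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, table.alt_depth / np.maximum(depth, 1), np.nan)
    return FrequencyMatrix(
        sites=table.sites.copy(),
        pools=list(table.pools),
        freq=freq.astype(float),
        total_depth=depth,
    )


def combine_pools(
    table: PoolVariantTable,
    members: Sequence[str],
    name: str,
    mode: str = "sum_counts",
) -> PoolVariantTable:
    """Merge pools into one by summing read counts per site.

    The member pools are removed and replaced by a single pool ``name``
    (appended after the remaining pools).  ``mode='sum_counts'`` (default)
    sums raw ref/alt depths, which weights members by their sequencing depth;
    ``mode='mean_freq'`` instead averages member frequencies unweighted and
    materialises them over the summed depth (rounded), for comparison with
    analyses that pooled frequencies rather than reads.
    """
    if not members:
        raise ValidationError("combine_pools: empty member list")
    idx = [table.pool_index(m) for m in members]
    if name in set(table.pools) - set(members):
        raise ValidationError(f"combine_pools: name {name!r} collides with an existing pool")
    if mode not in {"sum_counts", "mean_freq"}:
        raise ValidationError(f"combine_pools: unknown mode {mode!r}")
    keep = [j for j, p in enumerate(table.pools) if p not in set(members)]
    ref_members = table.ref_depth[:, idx]
    alt_members = table.alt_depth[:, idx]
    if mode == "sum_counts":
        new_ref = ref_members.sum(axis=1)
        new_alt = alt_members.sum(axis=1)
    else:
        depth = ref_members + alt_members
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(depth > 0, alt_members / np.maximum(depth, 1), np.nan)
        mean_f = np.nanmean(np.where(np.isnan(f), np.nan, f), axis=1)
        total = depth.sum(axis=1)
        new_alt = np.where(np.isnan(mean_f), 0, np.rint(mean_f * total)).astype(np.int64)
        new_ref = total - new_alt
    pools = [table.pools[j] for j in keep] + [name]
    ref_depth = np.column_stack([table.ref_depth[:, keep], new_ref])
    alt_depth = np.column_stack([table.alt_depth[:, keep], new_alt])
    return PoolVariantTable(
        sites=table.sites.copy(), pools=pools, ref_depth=ref_depth, alt_depth=alt_depth
    )


def fixed_allele_proportion(freqs: FrequencyMatrix, pool: str) -> float:
    """Proportion of sites fixed (p exactly 0 or 1) within one pool.

    The denominator is the number of sites with a defined frequency in that
    pool, i.e. the shared called-SNP set minus zero-depth entries.
    """
    p = freqs.pool_frequencies(pool)
    defined = np.isfinite(p)
    n = int(defined.sum())
    if n == 0:
        raise UndefinedResultError(
            f"fixed_allele_proportion: pool {pool!r} has no site with defined frequency"
        )
    fixed = (p[defined] == 0.0) | (p[defined] == 1.0)
    return float(fixed.sum() / n)
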