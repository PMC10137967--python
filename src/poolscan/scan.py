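"""Sliding-window genome scan and empirical-percentile outlier calling.

Per-SNP F_ST values are averaged in 500-kb windows that overlap by 50%
(step 250 kb), giving the windowed mean mF_ST.  Windows whose mF_ST lies
strictly above the 99th percentile of the empirical window distribution and
that contain more than ``min_snps`` SNPs are retained as outliers; runs of
overlapping or book-ended outlier windows merge into outlier regions.

Window coordinates are 0-based half-open ``[start, end)`` anchored at 0, so
the default parameters produce boundaries at multiples of 250 kb.  SNP
positions are compared directly against these coordinates: a SNP belongs to
every window with ``start <= pos < end``, hence a SNP at exactly 250,000
falls in both [0, 500k) and [250k, 750k).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from poolscan.errors import UndefinedResultError, ValidationError


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    n_snps: int = 0
    mfst: float = float("nan")

    @property
    def has_mfst(self) -> bool:
        return self.n_snps > 0 and np.isfinite(self.mfst)


@dataclass
class OutlierRegion:
    """Maximal run of merged outlier windows on one chromosome.

    ``total_snps`` sums the source windows' SNP counts; with overlapping
    windows a SNP shared by two retained windows is counted in each.
    """

    chrom: str
    start: int
    end: int
    windows: list[Window] = field(default_factory=list)

    @property
    def peak_mfst(self) -> float:
        if not self.windows:
            return float("nan")
        return max(w.mfst for w in self.windows)

    @property
    def total_snps(self) -> int:
        return sum(w.n_snps for w in self.windows)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class OutlierCall:
    """Result of :func:`call_outliers`: retained windows plus the threshold used."""

    retained: list[Window]
    threshold: float
    percentile: float
    min_snps: int
    n_windows_with_mfst: int


def make_windows(
    chrom_lengths: Mapping[str, int],
    window_size: int = 500_000,
    step: int = 250_000,
    keep_truncated: bool = True,
) -> list[Window]:
    """Sliding windows anchored at 0 for each chromosome.

    Windows start at 0, 1*step, 2*step, ... while start < length; a window
    extending past the chromosome end is truncated to its true span (set
    ``keep_truncated=False`` to drop truncated trailing windows instead).
    Output is ordered by (chromosome as given, start).
    """
    if step <= 0 or window_size <= 0:
        raise ValidationError("window_size and step must be positive")
    if step > window_size:
        raise ValidationError("step must not exceed window_size")
    windows: list[Window] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValidationError(f"chromosome {chrom!r} has non-positive length {length}")
        start = 0
        while start < length:
            end = min(start + window_size, length)
            if end < start + window_size and not keep_truncated:
                break
            windows.append(Window(chrom=chrom, start=start, end=end))
            start += step
    return windows


def window_mfst(windows: Sequence[Window], snp_fst: pd.DataFrame) -> list[Window]:
    """Fill n_snps and mF_ST for each window from a per-SNP F_ST track.

    ``snp_fst`` needs columns ``chrom``, ``pos``, ``fst`` sorted by
    (chromosome, position).  SNPs with undefined (NaN) F_ST contribute to
    neither the count nor the mean.
    """
    defined = snp_fst[np.isfinite(snp_fst["fst"].to_numpy(dtype=float))]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, sub in defined.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) < 0):
            raise ValidationError(f"snp_fst positions not sorted within {chrom!r}")
        fst = sub["fst"].to_numpy(dtype=float)
        cumsum = np.concatenate([[0.0], np.cumsum(fst)])
        by_chrom[str(chrom)] = (pos, cumsum)
    out: list[Window] = []
    for w in windows:
        if w.chrom not in by_chrom:
            out.append(replace(w, n_snps=0, mfst=float("nan")))
            continue
        pos, cumsum = by_chrom[w.chrom]
        lo = int(np.searchsorted(pos, w.start, side="left"))
        hi = int(np.searchsorted(pos, w.end, side="left"))
        n = hi - lo
        mfst = (cumsum[hi] - cumsum[lo]) / n if n > 0 else float("nan")
        out.append(replace(w, n_snps=n, mfst=mfst))
    return out


def call_outliers(
    windows: Sequence[Window],
    percentile: float = 99.0,
    min_snps: int = 200,
    percentile_after_min_snps: bool = False,
) -> OutlierCall:
    """Retain windows above the empirical mF_ST percentile with enough SNPs.

    The threshold is the given percentile (linear interpolation) of mF_ST
    over all windows with a defined mF_ST; by default it is computed before
    the SNP-count rule is applied (set ``percentile_after_min_snps=True``
    for the other order).  A window is retained iff its mF_ST is strictly
    above the threshold and its SNP count is strictly greater than
    ``min_snps``.
    """
    with_mfst = [w for w in windows if w.has_mfst]
    if not with_mfst:
        raise UndefinedResultError("call_outliers: no window has a defined mF_ST")
    pool = [w for w in with_mfst if w.n_snps > min_snps] if percentile_after_min_snps else with_mfst
    if not pool:
        raise UndefinedResultError(
            "call_outliers: no window passes the SNP-count rule, empirical distribution empty"
        )
    threshold = float(np.percentile(np.array([w.mfst for w in pool]), percentile))
    retained = [w for w in with_mfst if w.mfst > threshold and w.n_snps > min_snps]
    return OutlierCall(
        retained=retained,
        threshold=threshold,
        percentile=percentile,
        min_snps=min_snps,
        n_windows_with_mfst=len(with_mfst),
    )


def merge_outliers(retained: Sequence[Window]) -> list[OutlierRegion]:
    """Merge overlapping or book-ended retained windows into disjoint regions."""
    regions: list[OutlierRegion] = []
    for w in sorted(retained, key=lambda w: (w.chrom, w.start, w.end)):
        if regions and regions[-1].chrom == w.chrom and w.start <= regions[-1].end:
            last = regions[-1]
            last.end = max(last.end, w.end)
            last.windows.append(w)
        else:
            regions.append(OutlierRegion(chrom=w.chrom, start=w.start, end=w.end, windows=[w]))
    return regions


def windows_to_bed(windows: Sequence[Window], path: str | Path) -> None:
    """BED (0-based half-open) with mF_ST as the score and n_snps appended."""
    rows = [
        (w.chrom, w.start, w.end, f"win_{w.chrom}_{w.start}",
         "." if not np.isfinite(w.mfst) else format(w.mfst, ".8g"), w.n_snps)
        for w in windows
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def regions_to_bed(regions: Sequence[OutlierRegion], path: str | Path) -> None:
    rows = [
        (r.chrom, r.start, r.end, f"region_{r.chrom}_{r.start}",
         format(r.peak_mfst, ".8g"), r.total_snps)
        for r in regions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_regions_bed(path: str | Path) -> list[OutlierRegion]:
    """Read regions back from BED (first three columns used)."""
    regions: list[OutlierRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            regions.append(
                OutlierRegion(chrom=parts[0], start=int(parts[1]), end=int(parts[2]))
            )
    return regions
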