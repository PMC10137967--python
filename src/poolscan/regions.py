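"""Annotation of outlier regions: gene intersection and impact tallies.

Genes come from GFF3 or BED; intersection uses interval trees and reports a
gene for a region whenever the two intervals share at least one base pair
(strand ignored).  Variant-impact records — one row per predicted
consequence, emulating a Variant Effect Predictor summary — are tallied per
severity class both genome-wide and inside the outlier regions.  A SNP may
carry several consequence records (alternative transcripts); tallies count
records by default, with an optional unique-position mode.

Gene coordinates are held 0-based half-open internally: GFF3 input (1-based
inclusive) is converted on read, BED is used as-is.  Impact-record positions
are compared directly against region coordinates, matching the SNP-to-window
convention of :mod:`poolscan.scan`.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from poolscan.errors import FormatError, ValidationError
from poolscan.scan import OutlierRegion

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.name!r}: start {self.start} must be < end {self.end}"
            )


@dataclass
class GeneSet:
    genes: list[Gene]

    def __len__(self) -> int:
        return len(self.genes)

    def chroms(self) -> set[str]:
        return {g.chrom for g in self.genes}

    @classmethod
    def from_gff3(cls, path: str | Path, feature_type: str = "gene") -> "GeneSet":
        """Genes from GFF3; 1-based inclusive coordinates converted to 0-based half-open."""
        genes: list[Gene] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 9:
                    raise FormatError(f"{path}:{lineno}: GFF3 line has {len(parts)} fields, expected 9")
                chrom, _source, ftype, start, end, _score, strand, _phase, attrs = parts
                if ftype != feature_type:
                    continue
                name = None
                for item in attrs.split(";"):
                    key, _, value = item.partition("=")
                    if key in ("ID", "Name") and value:
                        name = value
                        if key == "Name":
                            break
                genes.append(
                    Gene(
                        name=name or f"{chrom}:{start}-{end}",
                        chrom=chrom,
                        start=int(start) - 1,
                        end=int(end),
                        strand=strand,
                    )
                )
        return cls(genes=genes)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneSet":
        genes: list[Gene] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 fields")
                name = parts[3] if len(parts) > 3 else f"{parts[0]}:{parts[1]}-{parts[2]}"
                strand = parts[5] if len(parts) > 5 else "."
                genes.append(
                    Gene(name=name, chrom=parts[0], start=int(parts[1]), end=int(parts[2]), strand=strand)
                )
        return cls(genes=genes)

    def to_gff3(self, path: str | Path) -> None:
        lines = ["##gff-version 3"]
        for g in self.genes:
            attrs = f"ID={g.name};Name={g.name}"
            lines.append(
                "\t".join(
                    [g.chrom, "poolscan", "gene", str(g.start + 1), str(g.end), ".",
                     g.strand, ".", attrs]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")

    def to_bed(self, path: str | Path) -> None:
        lines = [
            "\t".join([g.chrom, str(g.start), str(g.end), g.name, "0", g.strand])
            for g in self.genes
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def genes_in_regions(
    regions: Sequence[OutlierRegion], genes: GeneSet
) -> dict[tuple[str, int, int], list[Gene]]:
    """Genes overlapping each region by at least 1 bp, strand ignored.

    Returns a mapping from region key ``(chrom, start, end)`` to genes in
    deterministic (start, end, name) order; each gene appears at most once
    per region.  Chromosomes present in the gene set but absent from the
    regions are ignored with a warning.
    """
    region_chroms = {r.chrom for r in regions}
    orphan = genes.chroms() - region_chroms
    if orphan and regions:
        warnings.warn(
            f"genes on chromosomes absent from the region set ignored: {sorted(orphan)}",
            stacklevel=2,
        )
    trees: dict[str, IntervalTree] = {}
    for g in genes.genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    out: dict[tuple[str, int, int], list[Gene]] = {}
    for r in regions:
        hits = trees[r.chrom].overlap(r.start, r.end) if r.chrom in trees else set()
        found = sorted({iv.data for iv in hits}, key=lambda g: (g.start, g.end, g.name))
        out[(r.chrom, r.start, r.end)] = found
    return out


def write_region_genes(
    mapping: dict[tuple[str, int, int], list[Gene]], path: str | Path
) -> None:
    rows = [
        {
            "chrom": chrom,
            "start": start,
            "end": end,
            "n_genes": len(gs),
            "genes": ",".join(g.name for g in gs),
        }
        for (chrom, start, end), gs in mapping.items()
    ]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "n_genes", "genes"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# impact tables
# ---------------------------------------------------------------------------


def read_impact_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns chrom, pos, impact, consequence; classes validated."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "pos", "impact", "consequence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: impact table missing columns {missing}")
    validate_impact_table(df, source=str(path))
    return df


def validate_impact_table(df: pd.DataFrame, source: str = "impact table") -> None:
    bad = ~df["impact"].isin(IMPACT_CLASSES)
    if bad.any():
        row = df[bad].iloc[0]
        raise ValidationError(
            f"{source}: unknown impact class {row['impact']!r} at {row['chrom']}:{row['pos']}"
        )


@dataclass
class ImpactTally:
    """Per-class consequence counts genome-wide and within outlier regions."""

    overall: Counter
    in_regions: Counter
    unique_positions: bool = False

    @staticmethod
    def _pct(counts: Counter) -> dict[str, float]:
        total = sum(counts.values())
        if total == 0:
            return {c: 0.0 for c in IMPACT_CLASSES}
        return {c: 100.0 * counts.get(c, 0) / total for c in IMPACT_CLASSES}

    @property
    def overall_pct(self) -> dict[str, float]:
        return self._pct(self.overall)

    @property
    def in_regions_pct(self) -> dict[str, float]:
        return self._pct(self.in_regions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scope, counts, pct in (
            ("overall", self.overall, self.overall_pct),
            ("in_regions", self.in_regions, self.in_regions_pct),
        ):
            for cls in IMPACT_CLASSES:
                rows.append(
                    {"scope": scope, "impact": cls, "count": counts.get(cls, 0),
                     "percent": pct[cls]}
                )
        return pd.DataFrame(rows)


def impact_tally(
    regions: Sequence[OutlierRegion],
    impacts: pd.DataFrame,
    unique_positions: bool = False,
) -> ImpactTally:
    """Tally impact classes genome-wide and inside the outlier regions.

    Positions are assigned to regions point-in-interval.  By default every
    consequence record counts; ``unique_positions=True`` collapses records to
    one per (chrom, pos), keeping the most severe class at that position.
    """
    validate_impact_table(impacts)
    df = impacts
    if unique_positions:
        severity = {c: i for i, c in enumerate(IMPACT_CLASSES)}  # HIGH = 0 most severe
        df = (
            df.assign(_sev=df["impact"].map(severity))
            .sort_values(["chrom", "pos", "_sev"], kind="mergesort")
            .drop_duplicates(["chrom", "pos"], keep="first")
            .drop(columns="_sev")
        )
    overall = Counter(df["impact"])
    inside = np.zeros(len(df), dtype=bool)
    pos = df["pos"].to_numpy(dtype=np.int64)
    chrom = df["chrom"].to_numpy(dtype=object)
    for r in regions:
        inside |= (chrom == r.chrom) & (pos >= r.start) & (pos < r.end)
    in_regions = Counter(df.loc[inside, "impact"])
    return ImpactTally(overall=overall, in_regions=in_regions, unique_positions=unique_positions)
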