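"""Wright-Fisher simulator of pooled sequencing experiments.

The generator emulates the statistical structure of a hatchery broodstock
design: several breeding nuclei founded from one common base population,
each drifting independently for a number of discrete generations at a finite
effective size, then sequenced as DNA pools of a few dozen fish at moderate
depth.  Divergent selection can be planted at chosen loci in a chosen
nucleus; because windowed scans detect the hitchhiking footprint of a sweep
rather than a single site, the selection differential is applied to every
SNP within ``sweep_radius_bp`` of a planted locus.

The sampling model per SNP and pool has three layers:

1. nucleus allele frequency: a Wright-Fisher binomial trajectory with
   2 N_e allele copies per generation, starting from a shared founder
   frequency (uniform on a configurable range), with the deterministic
   selection update p' = p(1+s) / (p(1+s) + (1-p)) applied before each
   binomial draw at swept sites of the target nucleus;
2. pool composition: 2 * fish_per_pool allele copies drawn binomially from
   the nucleus frequency (equimolar contributions, no fish-level
   dispersion);
3. sequencing: total depth Poisson with the configured mean, alternate reads
   binomial at the pool frequency, optionally perturbed by a symmetric
   base-flip error rate (default 0).

``infinite_depth=True`` bypasses layers 2 and 3 and reports exact nucleus
frequencies over a fixed large depth — useful for truth checks such as
fixed-allele proportions.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from poolscan.errors import ValidationError
from poolscan.regions import IMPACT_CLASSES, Gene, GeneSet
from poolscan.variant_io import (
    PoolVariantTable,
    write_tsv,
    write_vcf,
)

_INFINITE_DEPTH = 1_000_000

_CONSEQUENCES: Mapping[str, tuple[str, ...]] = {
    "HIGH": ("stop_gained", "stop_lost", "splice_acceptor_variant", "splice_donor_variant"),
    "MODERATE": ("missense_variant", "inframe_deletion"),
    "LOW": ("synonymous_variant", "splice_region_variant"),
    "MODIFIER": ("intergenic_variant", "intron_variant", "upstream_gene_variant",
                 "downstream_gene_variant"),
}


@dataclass(frozen=True)
class PlantedLocus:
    """A site under divergent selection in one nucleus.

    ``s`` is the per-generation selection differential applied to the
    alternate allele; all SNPs within the sweep radius of ``pos`` experience
    it (hitchhiking around the swept site).
    """

    chrom: str
    pos: int
    s: float
    nucleus: str


@dataclass
class SimConfig:
    """Parameters of a simulated pool-seq experiment.

    Defaults emulate a three-nucleus hatchery design: a common base
    population, three nuclei (the first sequenced as three replicate pools,
    like A1/A2/A3), 30 fish per pool, ~60x mean depth, and moderate
    drift/bottleneck divergence (N_e = 100 diploids for 20 generations).
    """

    n_chromosomes: int = 3
    chrom_length_bp: int = 10_000_000
    n_snps: int = 6_000
    n_nuclei: int = 3
    fish_per_pool: int = 30
    effective_size_per_nucleus: int = 100
    generations: int = 20
    mean_depth: float = 60.0
    planted_loci: tuple[PlantedLocus, ...] = ()
    seed: int = 0
    pool_replicates: tuple[int, ...] | None = None  # per nucleus; default (3,1,1,...)
    founder_freq_range: tuple[float, float] = (0.05, 0.95)
    sweep_radius_bp: int = 250_000
    error_rate: float = 0.0
    low_quality_fraction: float = 0.02
    low_depth_fraction: float = 0.0
    infinite_depth: bool = False
    genes_per_mb: float = 10.0
    gene_length_bp: int = 20_000
    impact_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "MODIFIER": 0.9717,
            "LOW": 0.0202,
            "MODERATE": 0.0077,
            "HIGH": 0.0007,
        }
    )

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length_bp", "n_snps", "n_nuclei",
                     "fish_per_pool", "effective_size_per_nucleus"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"SimConfig.{name} must be > 0")
        if self.generations < 0:
            raise ValidationError("SimConfig.generations must be >= 0")
        if self.mean_depth <= 0:
            raise ValidationError("SimConfig.mean_depth must be > 0")
        lo, hi = self.founder_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValidationError("SimConfig.founder_freq_range must be within [0, 1]")
        if self.pool_replicates is not None and len(self.pool_replicates) != self.n_nuclei:
            raise ValidationError("pool_replicates must have one entry per nucleus")
        nuclei = set(self.nucleus_names())
        chroms = set(self.chrom_names())
        for locus in self.planted_loci:
            if not 0.0 <= locus.s <= 1.0:
                raise ValidationError(f"planted locus selection differential {locus.s} not in [0, 1]")
            if locus.nucleus not in nuclei:
                raise ValidationError(f"planted locus targets unknown nucleus {locus.nucleus!r}")
            if locus.chrom not in chroms or not 1 <= locus.pos <= self.chrom_length_bp:
                raise ValidationError(
                    f"planted locus {locus.chrom}:{locus.pos} outside simulated coordinates"
                )

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names()}

    def nucleus_names(self) -> list[str]:
        if self.n_nuclei > 26:
            raise ValidationError("at most 26 nuclei supported")
        return list(string.ascii_uppercase[: self.n_nuclei])

    def replicates(self) -> tuple[int, ...]:
        if self.pool_replicates is not None:
            return tuple(self.pool_replicates)
        if self.n_nuclei >= 1:
            return (3,) + (1,) * (self.n_nuclei - 1)
        return ()

    def pool_names(self) -> list[str]:
        names = []
        for nucleus, reps in zip(self.nucleus_names(), self.replicates()):
            if reps == 1:
                names.append(nucleus)
            else:
                names.extend(f"{nucleus}{i + 1}" for i in range(reps))
        return names

    def pool_nuclei(self) -> list[str]:
        """Nucleus of origin for each pool, aligned with :meth:`pool_names`."""
        out = []
        for nucleus, reps in zip(self.nucleus_names(), self.replicates()):
            out.extend([nucleus] * reps)
        return out


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated dataset."""

    sites: pd.DataFrame  # chrom, pos
    nuclei: list[str]
    base_frequencies: np.ndarray  # (n_snps,)
    final_frequencies: np.ndarray  # (n_snps, n_nuclei)
    planted_loci: tuple[PlantedLocus, ...]

    def nucleus_frequencies(self, nucleus: str) -> np.ndarray:
        return self.final_frequencies[:, self.nuclei.index(nucleus)]

    def to_frame(self) -> pd.DataFrame:
        df = self.sites[["chrom", "pos"]].copy()
        df["base_freq"] = self.base_frequencies
        for j, nucleus in enumerate(self.nuclei):
            df[f"freq_{nucleus}"] = self.final_frequencies[:, j]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")


@dataclass
class SimDataset:
    """Everything :func:`generate_dataset` produces."""

    variants: PoolVariantTable
    truth: SimTruth
    genes: GeneSet
    impacts: pd.DataFrame
    config: SimConfig


# ---------------------------------------------------------------------------
# elementary processes
# ---------------------------------------------------------------------------


def _check_freq(p: float, name: str = "p0") -> None:
    if not np.all(np.isfinite(p)) or np.any(np.asarray(p) < 0) or np.any(np.asarray(p) > 1):
        raise ValidationError(f"{name} must be a frequency in [0, 1], got {p!r}")


def simulate_drift(
    p0: float,
    effective_size: int,
    generations: int,
    replicates: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Endpoint frequencies of independent Wright-Fisher trajectories.

    Each generation draws the allele count binomially from 2 * effective_size
    trials at the current frequency; frequencies are absorbing at 0 and 1.
    """
    _check_freq(p0)
    if effective_size < 1:
        raise ValidationError("effective_size must be >= 1")
    if generations < 0 or replicates < 0:
        raise ValidationError("generations and replicates must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_copies = 2 * effective_size
    p = np.full(replicates, float(p0))
    for _ in range(generations):
        p = rng.binomial(n_copies, p) / n_copies
    return p


def simulate_selection_step(p: float | np.ndarray, s: float | np.ndarray) -> float | np.ndarray:
    """Deterministic one-generation selection update p' = p(1+s) / (p(1+s) + 1 - p)."""
    p_arr = np.asarray(p, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    _check_freq(p_arr, "p")
    if np.any(s_arr < 0) or np.any(s_arr > 1):
        raise ValidationError(f"selection differential must be in [0, 1], got {s!r}")
    out = p_arr * (1.0 + s_arr) / (p_arr * (1.0 + s_arr) + (1.0 - p_arr))
    return float(out) if np.isscalar(p) and np.isscalar(s) else out


def sample_pool_reads(
    true_freq: float,
    fish_per_pool: int,
    mean_depth: float,
    seed: int | np.random.Generator,
) -> tuple[int, int]:
    """Two-stage sampling of pooled reads at one site.

    The pool allele frequency is drawn binomially over 2 * fish_per_pool
    allele copies (finite pool), then total depth from a Poisson with the
    given mean and alternate reads binomially at the pool frequency.
    Returns (ref_reads, alt_reads).
    """
    _check_freq(true_freq, "true_freq")
    if fish_per_pool < 1:
        raise ValidationError("fish_per_pool must be >= 1")
    if mean_depth <= 0:
        raise ValidationError("mean_depth must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool_freq = rng.binomial(2 * fish_per_pool, true_freq) / (2 * fish_per_pool)
    depth = int(rng.poisson(mean_depth))
    alt = int(rng.binomial(depth, pool_freq)) if depth > 0 else 0
    return depth - alt, alt


# ---------------------------------------------------------------------------
# full dataset generation
# ---------------------------------------------------------------------------


def _snp_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = config.chrom_names()
    per_chrom = np.full(len(chroms), config.n_snps // len(chroms), dtype=int)
    per_chrom[: config.n_snps % len(chroms)] += 1
    frames = []
    for chrom, n in zip(chroms, per_chrom):
        if n > config.chrom_length_bp:
            raise ValidationError("more SNPs requested than base pairs available")
        pos = np.sort(rng.choice(config.chrom_length_bp, size=n, replace=False)) + 1
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos.astype(np.int64)}))
    return pd.concat(frames, ignore_index=True)


def _selection_mask(config: SimConfig, sites: pd.DataFrame, nucleus: str) -> tuple[np.ndarray, np.ndarray]:
    """(mask, s) of sites swept in ``nucleus`` by any planted locus."""
    chrom = sites["chrom"].to_numpy(dtype=object)
    pos = sites["pos"].to_numpy(dtype=np.int64)
    mask = np.zeros(len(sites), dtype=bool)
    s = np.zeros(len(sites), dtype=float)
    for locus in config.planted_loci:
        if locus.nucleus != nucleus:
            continue
        hit = (chrom == locus.chrom) & (np.abs(pos - locus.pos) <= config.sweep_radius_bp)
        mask |= hit
        s = np.where(hit, np.maximum(s, locus.s), s)
    return mask, s


def _evolve_nucleus(
    config: SimConfig,
    sites: pd.DataFrame,
    p0: np.ndarray,
    nucleus: str,
    rng: np.random.Generator,
) -> np.ndarray:
    n_copies = 2 * config.effective_size_per_nucleus
    mask, s = _selection_mask(config, sites, nucleus)
    p = p0.copy()
    for _ in range(config.generations):
        if mask.any():
            p = np.where(mask, simulate_selection_step(p, s), p)
        p = rng.binomial(n_copies, p) / n_copies
    return p


def _sample_pool_matrix(
    config: SimConfig, truth_freq: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised read sampling for one pool over all sites."""
    n = len(truth_freq)
    if config.infinite_depth:
        depth = np.full(n, _INFINITE_DEPTH, dtype=np.int64)
        alt = np.rint(truth_freq * _INFINITE_DEPTH).astype(np.int64)
        return depth - alt, alt
    copies = 2 * config.fish_per_pool
    pool_freq = rng.binomial(copies, truth_freq) / copies
    depth = rng.poisson(config.mean_depth, size=n)
    if config.low_depth_fraction > 0:
        low = rng.random(n) < config.low_depth_fraction
        depth = np.where(low, rng.poisson(config.mean_depth / 4, size=n), depth)
    if config.error_rate > 0:
        pool_freq = pool_freq * (1 - config.error_rate) + (1 - pool_freq) * config.error_rate
    alt = rng.binomial(depth, pool_freq)
    return (depth - alt).astype(np.int64), alt.astype(np.int64)


def _tile_genes(config: SimConfig) -> GeneSet:
    genes: list[Gene] = []
    n_per_chrom = max(1, int(round(config.genes_per_mb * config.chrom_length_bp / 1e6)))
    spacing = config.chrom_length_bp / n_per_chrom
    for chrom in config.chrom_names():
        for i in range(n_per_chrom):
            start = int(round(i * spacing))
            end = min(start + config.gene_length_bp, config.chrom_length_bp)
            if end <= start:
                continue
            genes.append(
                Gene(
                    name=f"gene_{chrom}_{i + 1:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if i % 2 == 0 else "-",
                )
            )
    return GeneSet(genes=genes)


def _impact_table(config: SimConfig, sites: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    classes = list(IMPACT_CLASSES)
    raw = np.array([float(config.impact_proportions.get(c, 0.0)) for c in classes])
    if raw.sum() <= 0:
        raise ValidationError("impact_proportions must have positive total mass")
    probs = raw / raw.sum()
    idx = rng.choice(len(classes), size=len(sites), p=probs)
    impact = [classes[i] for i in idx]
    consequence = [
        _CONSEQUENCES[c][rng.integers(len(_CONSEQUENCES[c]))] for c in impact
    ]
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "impact": impact,
            "consequence": consequence,
        }
    )


def generate_dataset(config: SimConfig) -> SimDataset:
    """Simulate a full pool-seq experiment with known ground truth.

    Fully reproducible: identical configs (including seed) yield identical
    datasets.
    """
    rng = np.random.default_rng(config.seed)
    sites = _snp_positions(config, rng)
    n = len(sites)
    lo, hi = config.founder_freq_range
    p0 = rng.uniform(lo, hi, size=n)

    nuclei = config.nucleus_names()
    final = np.column_stack(
        [_evolve_nucleus(config, sites, p0, nucleus, rng) for nucleus in nuclei]
    )
    truth = SimTruth(
        sites=sites.copy(),
        nuclei=nuclei,
        base_frequencies=p0,
        final_frequencies=final,
        planted_loci=tuple(config.planted_loci),
    )

    ref_cols, alt_cols = [], []
    for nucleus in config.pool_nuclei():
        ref, alt = _sample_pool_matrix(config, truth.nucleus_frequencies(nucleus), rng)
        ref_cols.append(ref)
        alt_cols.append(alt)

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    ref_allele = bases[ref_idx]
    alt_allele = bases[(ref_idx + rng.integers(1, 4, size=n)) % 4]  # always != ref

    qual = np.round(rng.uniform(150.0, 2000.0, size=n), 1)
    if config.low_quality_fraction > 0:
        fail = rng.random(n) < config.low_quality_fraction
        qual = np.where(fail, np.round(rng.uniform(20.0, 100.0, size=n), 1), qual)

    site_frame = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "ref": ref_allele,
            "alt": alt_allele,
            "qual": qual,
        }
    )
    variants = PoolVariantTable(
        sites=site_frame,
        pools=config.pool_names(),
        ref_depth=np.column_stack(ref_cols),
        alt_depth=np.column_stack(alt_cols),
    )
    genes = _tile_genes(config)
    impacts = _impact_table(config, sites, rng)
    return SimDataset(variants=variants, truth=truth, genes=genes, impacts=impacts, config=config)


def write_dataset(dataset: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact of a simulated dataset; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "variants.vcf",
        "tsv": outdir / "variants.tsv",
        "genes_gff3": outdir / "genes.gff3",
        "genes_bed": outdir / "genes.bed",
        "impacts": outdir / "impacts.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(dataset.variants, paths["vcf"])
    write_tsv(dataset.variants, paths["tsv"])
    dataset.genes.to_gff3(paths["genes_gff3"])
    dataset.genes.to_bed(paths["genes_bed"])
    dataset.impacts.to_csv(paths["impacts"], sep="\t", index=False)
    dataset.truth.to_tsv(paths["truth"])
    return paths
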