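"""End-to-end orchestration: simulate/load -> filter -> combine -> F_ST ->
window scan -> outlier regions -> annotation -> PCA.

A run is described by a declarative YAML config (:class:`RunConfig`); every
intermediate artifact is written to the output directory and recorded in a
manifest with SHA-256 hashes, so identical config + seed reproduce identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any, Mapping

import yaml

from poolscan import diffstats, pca, regions as regions_mod, scan, simulate, variant_io
from poolscan.errors import ValidationError

logger = logging.getLogger("poolscan")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    outdir: Path
    seed: int = 0
    simulate: simulate.SimConfig | None = None
    input_variants: Path | None = None
    input_genes: Path | None = None
    input_impacts: Path | None = None
    chrom_lengths: dict[str, int] | None = None
    combine: dict[str, list[str]] = field(default_factory=dict)
    min_quality: float = 100.0
    min_mean_depth: float = 40.0
    window_size: int = 500_000
    step: int = 250_000
    percentile: float = 99.0
    min_snps: int = 200
    comparisons: list[tuple[str, str]] | None = None
    max_components: int = 3

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        if "outdir" not in raw:
            raise ValidationError("run config needs an 'outdir'")
        sim_cfg = None
        if "simulate" in raw:
            sim_raw = dict(raw["simulate"])
            loci = tuple(
                simulate.PlantedLocus(**dict(item)) for item in sim_raw.pop("planted_loci", [])
            )
            if "planted_loci" not in sim_raw:
                sim_raw["planted_loci"] = loci
            if "pool_replicates" in sim_raw and sim_raw["pool_replicates"] is not None:
                sim_raw["pool_replicates"] = tuple(sim_raw["pool_replicates"])
            sim_cfg = simulate.SimConfig(**sim_raw)
        inp = dict(raw.get("input", {}))
        if sim_cfg is None and "variants" not in inp:
            raise ValidationError("run config needs either 'simulate' or 'input.variants'")
        filt = dict(raw.get("filter", {}))
        scan_cfg = dict(raw.get("scan", {}))
        pca_cfg = dict(raw.get("pca", {}))
        comparisons = raw.get("comparisons")
        if comparisons is not None:
            comparisons = [tuple(pair) for pair in comparisons]
            for pair in comparisons:
                if len(pair) != 2:
                    raise ValidationError(f"comparison {pair!r} must name exactly two pools")
        return cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            simulate=sim_cfg,
            input_variants=Path(inp["variants"]) if "variants" in inp else None,
            input_genes=Path(inp["genes"]) if "genes" in inp else None,
            input_impacts=Path(inp["impacts"]) if "impacts" in inp else None,
            chrom_lengths={str(k): int(v) for k, v in inp.get("chrom_lengths", {}).items()}
            or None,
            combine={str(k): list(v) for k, v in raw.get("combine", {}).items()},
            min_quality=float(filt.get("min_quality", 100.0)),
            min_mean_depth=float(filt.get("min_mean_depth", 40.0)),
            window_size=int(scan_cfg.get("window_size", 500_000)),
            step=int(scan_cfg.get("step", 250_000)),
            percentile=float(scan_cfg.get("percentile", 99.0)),
            min_snps=int(scan_cfg.get("min_snps", 200)),
            comparisons=comparisons,
            max_components=int(pca_cfg.get("max_components", 3)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def final_pool_names(self, pools: list[str]) -> list[str]:
        """Pool names after applying the combination map to ``pools``."""
        members = {m for ms in self.combine.values() for m in ms}
        out = [p for p in pools if p not in members]
        out.extend(self.combine.keys())
        return out

    def validate_pools(self, pools: list[str]) -> None:
        known = set(pools)
        for name, members in self.combine.items():
            for m in members:
                if m not in known:
                    raise ValidationError(f"combine target {name!r} references unknown pool {m!r}")
        final = set(self.final_pool_names(pools))
        for pair in self.comparisons or []:
            for p in pair:
                if p not in final:
                    raise ValidationError(f"comparison references unknown pool {p!r}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, seed: int) -> None:
        self.outdir = outdir
        self.data: dict[str, Any] = {"seed": seed, "stages": []}

    def add(self, stage: str, params: Mapping[str, Any], outputs: Mapping[str, Path]) -> None:
        entry = {
            "stage": stage,
            "params": dict(sorted(params.items())),
            "outputs": {
                name: {
                    "path": str(path.relative_to(self.outdir)),
                    "bytes": path.stat().st_size,
                    "sha256": _sha256(path),
                }
                for name, path in sorted(outputs.items())
            },
        }
        self.data["stages"].append(entry)
        logger.info("stage %s done (%d outputs)", stage, len(outputs))

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
        return path


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage; returns the manifest dictionary."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config.seed)

    # --- stage 1: obtain variants (simulate or load) -----------------------
    genes: regions_mod.GeneSet | None = None
    impacts = None
    if config.simulate is not None:
        sim_cfg = simulate.SimConfig(
            **{**config.simulate.__dict__, "seed": config.seed}
        )
        dataset = simulate.generate_dataset(sim_cfg)
        paths = simulate.write_dataset(dataset, outdir / "simulated")
        manifest.add("simulate", {"seed": config.seed, "n_snps": sim_cfg.n_snps}, paths)
        table = dataset.variants
        genes = dataset.genes
        impacts = dataset.impacts
        chrom_lengths = sim_cfg.chrom_lengths()
    else:
        assert config.input_variants is not None
        table = variant_io.read_variants(config.input_variants)
        manifest.add("load", {"variants": str(config.input_variants)}, {})
        if config.input_genes is not None:
            path = config.input_genes
            genes = (
                regions_mod.GeneSet.from_bed(path)
                if path.suffix.lower() == ".bed"
                else regions_mod.GeneSet.from_gff3(path)
            )
        if config.input_impacts is not None:
            impacts = regions_mod.read_impact_table(config.input_impacts)
        if config.chrom_lengths:
            chrom_lengths = config.chrom_lengths
        else:
            chrom_lengths = {
                str(chrom): int(sub["pos"].max())
                for chrom, sub in table.sites.groupby("chrom", sort=False)
            }
    config.validate_pools(table.pools)

    # --- stage 2: site filters --------------------------------------------
    filtered, report = variant_io.filter_sites(
        table, min_quality=config.min_quality, min_mean_depth=config.min_mean_depth
    )
    filtered_path = outdir / "filtered.vcf"
    variant_io.write_vcf(filtered, filtered_path)
    manifest.add(
        "filter",
        {
            "min_quality": config.min_quality,
            "min_mean_depth": config.min_mean_depth,
            "n_input": report.n_input,
            "n_retained": report.n_retained,
            "removed_not_biallelic": report.removed_not_biallelic,
            "removed_quality": report.removed_quality,
            "removed_depth": report.removed_depth,
        },
        {"filtered_vcf": filtered_path},
    )

    # --- stage 3: pool combination ----------------------------------------
    combined = filtered
    for name, members in config.combine.items():
        combined = variant_io.combine_pools(combined, members, name)
    if config.combine:
        combined_path = outdir / "combined.vcf"
        variant_io.write_vcf(combined, combined_path)
        manifest.add("combine", {k: ",".join(v) for k, v in config.combine.items()},
                     {"combined_vcf": combined_path})

    # --- stage 4: frequencies ---------------------------------------------
    freqs = variant_io.compute_frequencies(combined)
    freq_path = outdir / "frequencies.tsv"
    variant_io.write_frequencies(freqs, freq_path)
    fixed = {}
    for pool in freqs.pools:
        try:
            fixed[pool] = variant_io.fixed_allele_proportion(freqs, pool)
        except Exception:  # zero defined sites: leave out
            pass
    manifest.add("frequencies", {"fixed_allele_proportion": fixed}, {"frequencies": freq_path})

    # --- stage 5: pairwise FST, scan, annotation --------------------------
    comparisons = config.comparisons or list(combinations(sorted(combined.pools), 2))
    all_regions: dict[str, list[scan.OutlierRegion]] = {}
    for pool_a, pool_b in comparisons:
        tag = f"{pool_a}_vs_{pool_b}"
        result = diffstats.pairwise_fst(freqs, pool_a, pool_b)
        fst_path = outdir / f"fst_{tag}.tsv"
        diffstats.write_fst_tsv(result, fst_path)

        windows = scan.make_windows(chrom_lengths, config.window_size, config.step)
        windows = scan.window_mfst(windows, result.snps)
        call = scan.call_outliers(windows, percentile=config.percentile, min_snps=config.min_snps)
        merged = scan.merge_outliers(call.retained)
        all_regions[tag] = merged
        win_path = outdir / f"windows_{tag}.bed"
        reg_path = outdir / f"regions_{tag}.bed"
        scan.windows_to_bed(windows, win_path)
        scan.regions_to_bed(merged, reg_path)
        outputs = {"fst": fst_path, "windows": win_path, "regions": reg_path}

        if genes is not None:
            mapping = regions_mod.genes_in_regions(merged, genes)
            genes_path = outdir / f"region_genes_{tag}.tsv"
            regions_mod.write_region_genes(mapping, genes_path)
            outputs["region_genes"] = genes_path
        if impacts is not None:
            tally = regions_mod.impact_tally(merged, impacts)
            tally_path = outdir / f"impact_tally_{tag}.tsv"
            tally.to_frame().to_csv(tally_path, sep="\t", index=False, float_format="%.6g")
            outputs["impact_tally"] = tally_path

        manifest.add(
            f"scan_{tag}",
            {
                "global_fst_mean": result.global_fst_mean,
                "global_fst_ratio": result.global_fst_ratio,
                "n_snps_used": result.n_snps_used,
                "threshold": call.threshold,
                "n_outlier_windows": len(call.retained),
                "n_regions": len(merged),
            },
            outputs,
        )

    # --- stage 6: PCA ------------------------------------------------------
    pca_result = pca.run_pca(freqs, max_components=config.max_components)
    scores_path, var_path = pca.write_pca(pca_result, outdir / "pca")
    manifest.add(
        "pca",
        {
            "components_kept": pca_result.components_kept,
            "explained_pct": [round(v, 6) for v in pca_result.explained_variance_pct],
            "n_sites_used": pca_result.n_sites_used,
        },
        {"scores": scores_path, "variance": var_path},
    )

    manifest_path = manifest.write()
    logger.info("manifest written to %s", manifest_path)
    return manifest.data


def setup_logging(level: str = "INFO") -> None:
    """Structured logs to stderr; results go only to files."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
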