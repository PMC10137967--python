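from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from poolscan.simulate import PlantedLocus, SimConfig, generate_dataset
from poolscan.variant_io import PoolVariantTable

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


def make_table(
    rows: list[tuple], pools: list[str], depths: list[list[tuple[int, int]]]
) -> PoolVariantTable:
    """Build a small table from (chrom, pos, ref, alt, qual) rows and
    per-site lists of (ref_depth, alt_depth) pairs, one pair per pool."""
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual"])
    ref = np.array([[d[0] for d in site] for site in depths], dtype=np.int64)
    alt = np.array([[d[1] for d in site] for site in depths], dtype=np.int64)
    return PoolVariantTable(sites=sites, pools=pools, ref_depth=ref, alt_depth=alt)


@pytest.fixture(scope="session")
def demo_dataset():
    """Three-nuclei pooled experiment with one planted sweep in nucleus B."""
    config = SimConfig(
        n_chromosomes=3,
        chrom_length_bp=10_000_000,
        n_snps=4_000,
        n_nuclei=3,
        effective_size_per_nucleus=100,
        generations=20,
        planted_loci=(PlantedLocus("chr1", 5_000_000, 0.3, "B"),),
        seed=11,
    )
    return generate_dataset(config)
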