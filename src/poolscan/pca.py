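"""Pool-level principal component analysis on allele frequencies.

Observations are DNA pools, variables are per-site alternate-allele
frequencies.  Sites with a missing frequency in any pool are dropped
(complete cases), the site columns are centered but not scaled, and scores
come from the singular-value decomposition of the centered matrix — the same
model as a centered, unscaled ``prcomp``.  Component signs are fixed by a
deterministic convention: the loading of largest magnitude on each component
is made positive (ties broken by the first such site).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from poolscan.errors import UndefinedResultError
from poolscan.variant_io import FrequencyMatrix


@dataclass
class PcaResult:
    """Scores and explained variance of a pool-level PCA.

    ``explained_variance_pct`` is per kept component, as a percentage of the
    total variance of the centered matrix (so the kept components sum to at
    most 100, and to 100 when all informative components are kept).
    """

    coordinates: pd.DataFrame  # pools x PC1..PCk
    explained_variance_pct: np.ndarray
    component_variances: np.ndarray  # all informative components, not just kept
    total_variance: float
    components_kept: int
    n_sites_used: int
    n_sites_dropped: int

    @property
    def pools(self) -> list[str]:
        return list(self.coordinates.index)


def run_pca(freqs: FrequencyMatrix, max_components: int = 3) -> PcaResult:
    """PCA of pools on the complete-case alternate-allele frequency matrix."""
    if len(freqs.pools) < 2:
        raise UndefinedResultError("run_pca: need at least 2 pools")
    complete = np.isfinite(freqs.freq).all(axis=1)
    n_used = int(complete.sum())
    if n_used == 0:
        raise UndefinedResultError("run_pca: no site has a defined frequency in every pool")
    x = freqs.freq[complete].T  # pools x sites
    n_pools = x.shape[0]
    centered = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # informative rank: at most pools - 1 after centering
    rank = min(n_pools - 1, n_used)
    u, s, vt = u[:, :rank], s[:rank], vt[:rank]
    # sign convention: largest-magnitude loading positive
    for j in range(rank):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u * s
    variances = s**2 / max(n_pools - 1, 1)
    total = float(centered.var(axis=0, ddof=1).sum()) if n_pools > 1 else 0.0
    k = min(max_components, rank)
    coordinates = pd.DataFrame(
        scores[:, :k], index=list(freqs.pools), columns=[f"PC{j + 1}" for j in range(k)]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * variances[:k] / total if total > 0 else np.zeros(k)
    return PcaResult(
        coordinates=coordinates,
        explained_variance_pct=np.asarray(pct, dtype=float),
        component_variances=variances,
        total_variance=total,
        components_kept=k,
        n_sites_used=n_used,
        n_sites_dropped=int((~complete).sum()),
    )


def write_pca(result: PcaResult, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>_scores.tsv`` and ``<prefix>_variance.tsv``."""
    prefix = Path(prefix)
    scores_path = prefix.with_name(prefix.name + "_scores.tsv")
    var_path = prefix.with_name(prefix.name + "_variance.tsv")
    df = result.coordinates.copy()
    df.insert(0, "pool", df.index)
    df.to_csv(scores_path, sep="\t", index=False, float_format="%.8g")
    pd.DataFrame(
        {
            "component": [f"PC{j + 1}" for j in range(result.components_kept)],
            "explained_pct": result.explained_variance_pct,
        }
    ).to_csv(var_path, sep="\t", index=False, float_format="%.8g")
    return scores_path, var_path


def plot_pca(result: PcaResult, path: str | Path) -> None:
    """PC1-PC2 (and PC1-PC3 when present) scatter; plumbing only."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("PC1", "PC2")] if result.components_kept >= 2 else [("PC1", "PC1")]
    if result.components_kept >= 3:
        panels.append(("PC1", "PC3"))
    n_panels = len(panels)
    fig, axes = plt.subplots(1, n_panels, figsize=(5 * n_panels, 4), squeeze=False)
    for ax, (cx, cy) in zip(axes[0], panels):
        ax.scatter(result.coordinates[cx], result.coordinates[cy])
        for pool, row in result.coordinates.iterrows():
            ax.annotate(pool, (row[cx], row[cy]), fontsize=8)
        ax.set_xlabel(cx)
        ax.set_ylabel(cy)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
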