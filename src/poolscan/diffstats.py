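"""Pairwise F_ST from pooled allele frequencies.

Per-SNP differentiation between two DNA pools follows the pooled-read
adaptation of the Karlsson et al. estimator.  With alternate-allele
frequencies p1, p2 (q = 1 - p) at marker k,

    N_k = p1 (q2 - q1) + p2 (q1 - q2)
    D_k = p1 q2 + p2 q1
    F_ST(k) = N_k / D_k

Algebraically N_k = (p1 - p2)^2 and D_k = p1 + p2 - 2 p1 p2, so each defined
per-SNP value lies in [0, 1]; D_k = 0 exactly when both pools are fixed for
the same allele, in which case the SNP carries no differentiation
information and its F_ST is undefined.

Two global summaries are reported for every pairwise comparison:

* ``global_fst_mean`` — the arithmetic mean of defined per-SNP values
  ("averaging the F_ST calculated for each SNP"), used for windowed scans;
* ``global_fst_ratio`` — the ratio of sums sum(N_k) / sum(D_k), whose
  expectation under pure drift equals the drift fixation index
  1 - (1 - 1/(2 N_e))^t, which makes it the right quantity for calibration
  against Wright-Fisher theory.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from poolscan.errors import UndefinedResultError, ValidationError
from poolscan.variant_io import FrequencyMatrix


@dataclass(frozen=True)
class SnpFst:
    """Differentiation record for a single SNP."""

    p1: float
    p2: float
    nk: float
    dk: float
    fst: float  # NaN when dk == 0
    chrom: str | None = None
    pos: int | None = None

    @property
    def q1(self) -> float:
        return 1.0 - self.p1

    @property
    def q2(self) -> float:
        return 1.0 - self.p2


@dataclass
class PairwiseFstResult:
    """Per-SNP and global F_ST for one pool pair."""

    pool_a: str
    pool_b: str
    snps: pd.DataFrame  # columns: chrom, pos, p1, p2, nk, dk, fst
    global_fst_mean: float
    global_fst_ratio: float
    n_snps_used: int
    n_snps_undefined: int
    n_snps_missing: int  # sites skipped because either pool had no depth


def karlsson_terms(
    p1: np.ndarray | float, p2: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (N_k, D_k, F_ST) from the pooled-frequency formula.

    F_ST is NaN wherever D_k == 0.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q1 = 1.0 - p1
    q2 = 1.0 - p2
    nk = p1 * (q2 - q1) + p2 * (q1 - q2)
    dk = p1 * q2 + p2 * q1
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(dk > 0, nk / np.where(dk > 0, dk, 1.0), np.nan)
    return nk, dk, fst


def snp_fst(p1: float, p2: float, chrom: str | None = None, pos: int | None = None) -> SnpFst:
    """Per-SNP F_ST record for a single pair of pooled frequencies."""
    for name, p in (("p1", p1), ("p2", p2)):
        if not np.isfinite(p) or not 0.0 <= p <= 1.0:
            raise ValidationError(f"snp_fst: {name}={p!r} is not a frequency in [0, 1]")
    nk, dk, fst = karlsson_terms(p1, p2)
    return SnpFst(
        p1=float(p1), p2=float(p2), nk=float(nk), dk=float(dk), fst=float(fst),
        chrom=chrom, pos=pos,
    )


def pairwise_fst(freqs: FrequencyMatrix, pool_a: str, pool_b: str) -> PairwiseFstResult:
    """Per-SNP and global F_ST between two pools of a frequency matrix.

    Sites with a missing frequency in either pool are skipped and counted in
    ``n_snps_missing``; sites where both pools are fixed for the same allele
    (D_k = 0) are kept in the per-SNP table with NaN F_ST but excluded from
    both global summaries.
    """
    p1 = freqs.pool_frequencies(pool_a)
    p2 = freqs.pool_frequencies(pool_b)
    both = np.isfinite(p1) & np.isfinite(p2)
    if not both.any():
        raise UndefinedResultError(
            f"pairwise_fst: no site with defined frequencies in both "
            f"{pool_a!r} and {pool_b!r}"
        )
    nk, dk, fst = karlsson_terms(p1[both], p2[both])
    snps = pd.DataFrame(
        {
            "chrom": freqs.sites["chrom"].to_numpy()[both],
            "pos": freqs.sites["pos"].to_numpy()[both],
            "p1": p1[both],
            "p2": p2[both],
            "nk": nk,
            "dk": dk,
            "fst": fst,
        }
    )
    defined = np.isfinite(fst)
    n_used = int(defined.sum())
    if n_used == 0:
        raise UndefinedResultError(
            f"pairwise_fst: every shared site between {pool_a!r} and {pool_b!r} "
            "is fixed for the same allele (F_ST undefined)"
        )
    return PairwiseFstResult(
        pool_a=pool_a,
        pool_b=pool_b,
        snps=snps,
        global_fst_mean=float(fst[defined].mean()),
        global_fst_ratio=float(nk[defined].sum() / dk[defined].sum()),
        n_snps_used=n_used,
        n_snps_undefined=int((~defined).sum()),
        n_snps_missing=int((~both).sum()),
    )


def write_fst_tsv(result: PairwiseFstResult, path: str | Path) -> None:
    result.snps.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_fst_bed(result: PairwiseFstResult, path: str | Path) -> None:
    """Per-SNP F_ST as a BED score track (0-based half-open point intervals)."""
    df = result.snps
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"].astype(int) - 1,
            "end": df["pos"].astype(int),
            "name": [f"snp{i}" for i in range(len(df))],
            "score": df["fst"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False, float_format="%.8g")
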