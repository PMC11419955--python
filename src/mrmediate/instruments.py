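"""Instrumental-variable selection.

Candidate instruments pass a genome-wide p-value screen (default P < 1e-5),
are pruned to approximate linkage independence by greedy clumping (r^2 <
0.001 within a 10,000 kb window), filtered on minor-allele frequency
(MAF > 0.01), and finally screened for weak-instrument bias with the
F statistic

    F = R^2 (N - K - 1) / (K (1 - R^2)),

where R^2 is the cumulative exposure variance explained by the K instruments
and N the exposure sample size.  Instruments with a single-SNP F below 10 are
removed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import HarmonizedSet, InstrumentSet, LDMatrix, SummaryStats
from .errors import (
    DegenerateInputError,
    EmptyInputError,
    MissingLDError,
)

__all__ = [
    "select_candidates",
    "clump",
    "maf_filter",
    "f_statistic",
    "per_snp_r2",
    "build_instrument_set",
]


def select_candidates(stats: SummaryStats, p_threshold: float = 1e-5) -> SummaryStats:
    """Retain records with p-value strictly below the threshold, in order.

    Raises :class:`EmptyInputError` when nothing passes.
    """
    if not (0 < p_threshold < 1):
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    mask = pd.to_numeric(stats.df["pval"], errors="coerce") < p_threshold
    if not mask.any():
        raise EmptyInputError(
            f"{stats.trait_id}: no variants pass p < {p_threshold:g}"
        )
    return SummaryStats(stats.trait_id, stats.df.loc[mask], validate=False)


def clump(
    candidates: SummaryStats,
    ld: LDMatrix,
    r2_max: float = 0.001,
    window_kb: float = 10000,
) -> SummaryStats:
    """Greedy LD clumping.

    Sort candidates by ascending p-value (ties broken by variant id);
    repeatedly keep the best remaining variant and discard every remaining
    variant on the same chromosome within ``window_kb`` of it whose r^2 with
    it exceeds ``r2_max``.  The window never spans chromosomes.

    Raises :class:`MissingLDError` if any candidate is absent from ``ld``.
    """
    df = candidates.df
    missing = [s for s in df["snp"] if s not in ld]
    if missing:
        raise MissingLDError(
            f"{len(missing)} candidate(s) missing from LD matrix: {missing[:10]}"
        )
    order = df.sort_values(["pval", "snp"], kind="mergesort")
    remaining = list(order.index)
    pos = pd.to_numeric(df["pos"], errors="coerce")
    chrom = df["chrom"].astype(str)
    window_bp = window_kb * 1000.0
    kept: list = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        best_snp = df.at[best, "snp"]
        survivors = []
        for idx in remaining:
            same_chrom = chrom.at[idx] == chrom.at[best]
            in_window = (
                same_chrom
                and np.isfinite(pos.at[idx])
                and np.isfinite(pos.at[best])
                and abs(pos.at[idx] - pos.at[best]) <= window_bp
            )
            if in_window and ld.lookup(best_snp, df.at[idx, "snp"]) > r2_max:
                continue
            survivors.append(idx)
        remaining = survivors
    kept_ids = set(df.loc[kept, "snp"])
    # preserve the candidates' original row order
    mask = df["snp"].isin(kept_ids)
    return SummaryStats(candidates.trait_id, df.loc[mask], validate=False)


def maf_filter(stats: SummaryStats, maf_min: float = 0.01) -> SummaryStats:
    """Retain records with min(eaf, 1-eaf) strictly above ``maf_min``.

    Records with missing eaf are retained (frequency unknown, not filterable);
    their count is available by comparing lengths.
    """
    if not (0 < maf_min < 0.5):
        raise ValueError(f"maf_min must lie in (0, 0.5), got {maf_min}")
    eaf = pd.to_numeric(stats.df["eaf"], errors="coerce")
    maf = np.minimum(eaf, 1 - eaf)
    mask = (maf > maf_min) | eaf.isna()
    return SummaryStats(stats.trait_id, stats.df.loc[mask], validate=False)


def f_statistic(r2_total: float, n: float, k: int) -> float:
    """Instrument-strength F statistic, R^2 (N-K-1) / (K (1-R^2))."""
    if not (0 <= r2_total < 1):
        raise ValueError(f"r2_total must lie in [0, 1), got {r2_total}")
    if n <= k + 1:
        raise DegenerateInputError(
            f"sample size n={n} must exceed k+1={k + 1} instruments"
        )
    return float(r2_total * (n - k - 1) / (k * (1 - r2_total)))


def per_snp_r2(
    beta: float, eaf: float | None, se: float | None = None, n: float | None = None
) -> tuple[float, bool]:
    """Exposure variance explained by one SNP, assuming a standardized trait.

    Primary form 2 * eaf * (1-eaf) * beta^2; when eaf is missing, falls back
    to beta^2 / (beta^2 + n * se^2).  Returns (r2, used_fallback).
    """
    if eaf is not None and np.isfinite(eaf):
        return float(2.0 * eaf * (1.0 - eaf) * beta**2), False
    if se is None or n is None or not np.isfinite(se) or not np.isfinite(n):
        raise ValueError("per-SNP r2 needs eaf, or se and n for the fallback")
    return float(beta**2 / (beta**2 + n * se**2)), True


def build_instrument_set(
    harmonized: HarmonizedSet,
    exposure_n: float,
    f_min: float = 10.0,
) -> InstrumentSet:
    """Assemble the final instrument set, removing per-SNP weak instruments.

    Each SNP's own F (k=1 in the F formula) is compared against ``f_min``;
    weak SNPs are removed before the set-level R^2 and F are computed.

    Raises :class:`EmptyInputError` when every SNP is weak.
    """
    flags: list[str] = []
    r2 = np.empty(harmonized.nsnp)
    for j in range(harmonized.nsnp):
        r2_j, fb = per_snp_r2(
            harmonized.bx[j],
            harmonized.eaf[j] if np.isfinite(harmonized.eaf[j]) else None,
            se=harmonized.se_x[j],
            n=exposure_n,
        )
        r2[j] = min(r2_j, 1 - 1e-12)
        if fb:
            flags.append(f"r2_fallback:{harmonized.snp_ids[j]}")
    per_f = r2 * (exposure_n - 2) / (1 - r2)
    strong = per_f >= f_min
    if not strong.any():
        raise EmptyInputError(
            f"all {harmonized.nsnp} instruments weak (per-SNP F < {f_min})"
        )
    if not strong.all():
        flags.append(f"removed_weak:{int((~strong).sum())}")
    kept = harmonized.subset(strong)
    r2_total = float(min(r2[strong].sum(), 1 - 1e-12))
    k = kept.nsnp
    f_stat = f_statistic(r2_total, exposure_n, k)
    return InstrumentSet(
        harmonized=kept,
        k=k,
        r2_total=r2_total,
        f_stat=f_stat,
        per_snp_f=per_f[strong],
        flags=flags,
    )
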