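"""Core containers for summary-statistics MR analyses.

The pipeline moves through three shapes of data: per-trait GWAS summary
statistics (:class:`SummaryStats`), exposure-outcome effect pairs aligned to a
shared effect allele (:class:`HarmonizedSet`), and per-method causal estimates
(:class:`MREstimate` and the five-method :class:`MRPanel`).  All tables are
backed by pandas; effect sizes are per-allele betas, on the log-odds scale for
binary traits.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

NUCLEOTIDES = frozenset("ACGT")

#: canonical column order for summary-statistics tables
SUMSTAT_COLUMNS = [
    "snp",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_REQUIRED = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]


@dataclass
class LoadReport:
    """Row accounting for one summary-statistics load or clean pass."""

    n_read: int = 0
    n_kept: int = 0
    reasons: Counter = field(default_factory=Counter)

    @property
    def n_dropped(self) -> int:
        return self.n_read - self.n_kept


def _is_snp_allele(a: object) -> bool:
    return isinstance(a, str) and a in NUCLEOTIDES


class SummaryStats:
    """One GWAS trait's per-SNP association records.

    Parameters
    ----------
    trait_id : str
        Label for the trait (e.g. a GWAS accession or a simulated trait name).
    df : pandas.DataFrame
        Table with columns ``snp, chrom, pos, effect_allele, other_allele,
        eaf, beta, se, pval, n``.  ``chrom``/``pos``/``eaf``/``n`` may contain
        missing values; the rest are mandatory.

    The constructor validates invariants (unique variant ids, finite beta,
    se > 0, p in (0, 1], eaf in (0, 1) or missing, single-nucleotide alleles
    with effect != other) and raises :class:`ValidationError` on violation.
    Use :meth:`clean` to drop offending rows instead and obtain a report.
    """

    def __init__(self, trait_id: str, df: pd.DataFrame, validate: bool = True):
        self.trait_id = str(trait_id)
        df = df.reset_index(drop=True)
        for col in SUMSTAT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.df = df[SUMSTAT_COLUMNS].copy()
        if validate:
            bad = _invalid_mask(self.df)
            if bad.any():
                reasons = _invalid_reasons(self.df, bad)
                raise ValidationError(
                    f"{trait_id}: {int(bad.sum())} invalid rows: "
                    + ", ".join(f"{r} ({c})" for r, c in reasons.most_common())
                )
            if self.df["snp"].duplicated().any():
                dups = self.df.loc[self.df["snp"].duplicated(), "snp"].tolist()
                raise ValidationError(f"{trait_id}: duplicate variant ids {dups[:5]}")

    @classmethod
    def clean(cls, trait_id: str, df: pd.DataFrame) -> tuple["SummaryStats", LoadReport]:
        """Build a SummaryStats by dropping invalid rows, with accounting."""
        df = df.reset_index(drop=True)
        for col in SUMSTAT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[SUMSTAT_COLUMNS]
        report = LoadReport(n_read=len(df))
        bad = _invalid_mask(df)
        report.reasons = _invalid_reasons(df, bad)
        kept = df.loc[~bad].copy()
        dup = kept["snp"].duplicated()
        if dup.any():
            report.reasons["duplicate_id"] = int(dup.sum())
            kept = kept.loc[~dup]
        report.n_kept = len(kept)
        return cls(trait_id, kept, validate=False), report

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask_or_ids) -> "SummaryStats":
        """Restrict to a boolean mask (aligned to df) or an id sequence."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and getattr(
            mask_or_ids, "dtype", None
        ) == bool:
            sub = self.df.loc[np.asarray(mask_or_ids)]
        else:
            ids = set(mask_or_ids)
            sub = self.df.loc[self.df["snp"].isin(ids)]
        return SummaryStats(self.trait_id, sub, validate=False)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp"].tolist()

    def sample_size(self) -> float | None:
        """Representative sample size: median of the n column, if present."""
        n = pd.to_numeric(self.df["n"], errors="coerce")
        if n.notna().any():
            return float(n.median())
        return None


def _invalid_mask(df: pd.DataFrame) -> pd.Series:
    beta = pd.to_numeric(df["beta"], errors="coerce")
    se = pd.to_numeric(df["se"], errors="coerce")
    pval = pd.to_numeric(df["pval"], errors="coerce")
    eaf = pd.to_numeric(df["eaf"], errors="coerce")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    ea = df["effect_allele"]
    oa = df["other_allele"]
    bad = pd.Series(False, index=df.index)
    bad |= df["snp"].isna() | (df["snp"].astype(str).str.len() == 0)
    bad |= ~beta.apply(np.isfinite).astype(bool)
    bad |= ~(se > 0) | ~se.apply(np.isfinite).astype(bool)
    bad |= ~((pval > 0) & (pval <= 1))
    bad |= df["eaf"].notna() & ~((eaf > 0) & (eaf < 1))
    bad |= df["pos"].notna() & ~(pos >= 1)
    ok_alleles = ea.map(_is_snp_allele) & oa.map(_is_snp_allele) & (ea != oa)
    bad |= ~ok_alleles.astype(bool)
    return bad


def _invalid_reasons(df: pd.DataFrame, bad: pd.Series) -> Counter:
    reasons: Counter = Counter()
    if not bad.any():
        return reasons
    sub = df.loc[bad]
    se = pd.to_numeric(sub["se"], errors="coerce")
    pval = pd.to_numeric(sub["pval"], errors="coerce")
    beta = pd.to_numeric(sub["beta"], errors="coerce")
    eaf = pd.to_numeric(sub["eaf"], errors="coerce")
    for idx in sub.index:
        ea, oa = sub.at[idx, "effect_allele"], sub.at[idx, "other_allele"]
        if not (_is_snp_allele(ea) and _is_snp_allele(oa)):
            reasons["non_snp_alleles"] += 1
        elif ea == oa:
            reasons["identical_alleles"] += 1
        elif not np.isfinite(beta.at[idx]):
            reasons["non_finite_beta"] += 1
        elif not (se.at[idx] > 0):
            reasons["nonpositive_se"] += 1
        elif not (0 < pval.at[idx] <= 1):
            reasons["invalid_pval"] += 1
        elif pd.notna(sub.at[idx, "eaf"]) and not (0 < eaf.at[idx] < 1):
            reasons["invalid_eaf"] += 1
        else:
            reasons["other"] += 1
    return reasons


@dataclass
class HarmonizedSet:
    """Exposure/outcome effect pairs aligned to a shared effect allele."""

    exposure_id: str
    outcome_id: str
    snp_ids: list[str]
    bx: np.ndarray
    se_x: np.ndarray
    by: np.ndarray
    se_y: np.ndarray
    eaf: np.ndarray
    n_dropped: Counter = field(default_factory=Counter)
    dropped_snps: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        for name in ("bx", "se_x", "by", "se_y", "eaf"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.snp_ids)
        if k < 1:
            raise ValidationError("harmonized set must retain at least one SNP")
        for name in ("bx", "se_x", "by", "se_y", "eaf"):
            if len(getattr(self, name)) != k:
                raise ValidationError(f"harmonized arrays unequal length ({name})")

    @property
    def nsnp(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[bool] | Sequence[str]) -> "HarmonizedSet":
        keep = np.asarray(keep)
        if keep.dtype != bool:
            keep = np.isin(np.asarray(self.snp_ids, dtype=object), keep)
        return HarmonizedSet(
            self.exposure_id,
            self.outcome_id,
            [s for s, k in zip(self.snp_ids, keep) if k],
            self.bx[keep],
            self.se_x[keep],
            self.by[keep],
            self.se_y[keep],
            self.eaf[keep],
            n_dropped=Counter(self.n_dropped),
            dropped_snps=dict(self.dropped_snps),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp": self.snp_ids,
                "bx": self.bx,
                "se_x": self.se_x,
                "by": self.by,
                "se_y": self.se_y,
                "eaf": self.eaf,
            }
        )


class LDMatrix:
    """Squared-correlation (r^2) matrix over a SNP panel.

    Symmetric, unit diagonal, entries in [0, 1].
    """

    def __init__(self, snp_ids: Sequence[str], r2: np.ndarray):
        self.snp_ids = list(snp_ids)
        r2 = np.asarray(r2, dtype=float)
        k = len(self.snp_ids)
        if r2.shape != (k, k):
            raise ValidationError(f"r2 matrix shape {r2.shape} != ({k}, {k})")
        if not np.allclose(r2, r2.T):
            raise ValidationError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0):
            raise ValidationError("r2 diagonal must be 1")
        if np.any(r2 < 0) or np.any(r2 > 1 + 1e-12):
            raise ValidationError("r2 entries must lie in [0, 1]")
        self.r2 = r2
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids)

    @classmethod
    def read(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float))

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class InstrumentSet:
    """Selected instrumental variables with strength summaries."""

    harmonized: HarmonizedSet
    k: int
    r2_total: float
    f_stat: float
    per_snp_f: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class MREstimate:
    """One method's causal estimate on the log scale, with OR and 95% CI."""

    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    flags: list[str] = field(default_factory=list)

    @property
    def or_(self) -> float:
        return float(math.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(math.exp(self.beta - 1.96 * self.se))

    @property
    def ci_high(self) -> float:
        return float(math.exp(self.beta + 1.96 * self.se))

    def format_or(self, digits: int = 3) -> str:
        """The report-style "OR (CI low, CI high)" string."""
        return (
            f"{self.or_:.{digits}f} "
            f"({self.ci_low:.{digits}f}, {self.ci_high:.{digits}f})"
        )


@dataclass
class HeterogeneityResult:
    q: float
    df: int
    pval: float
    reference: str = "ivw"


@dataclass
class PleiotropyResult:
    intercept: float
    se: float
    pval: float


@dataclass
class LeaveOneOutResult:
    table: pd.DataFrame  # columns: snp, beta, se, pval; last row snp == "All"

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MRPanel:
    """Five-method causal-estimate bundle for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    estimates: dict[str, MREstimate]
    heterogeneity: dict[str, HeterogeneityResult] = field(default_factory=dict)
    pleiotropy: PleiotropyResult | None = None
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def nsnp(self) -> int:
        return next(iter(self.estimates.values())).nsnp

    def ivw(self) -> MREstimate | None:
        return self.estimates.get("IVW") or self.estimates.get("Wald")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, est in self.estimates.items():
            rows.append(
                {
                    "exposure": self.exposure_id,
                    "outcome": self.outcome_id,
                    "method": m,
                    "nsnp": est.nsnp,
                    "beta": est.beta,
                    "se": est.se,
                    "pval": est.pval,
                    "or": est.or_,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class MediationResult:
    """Two-step MR decomposition of a total effect into indirect and direct."""

    beta1: float
    se1: float
    beta2: float
    se2: float
    beta_all: float
    se_all: float
    indirect: float
    se_indirect: float
    direct: float
    proportion: float
    proportion_ci: tuple[float, float]
    pval_indirect: float
    flags: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "beta1": self.beta1,
                    "se1": self.se1,
                    "beta2": self.beta2,
                    "se2": self.se2,
                    "beta_all": self.beta_all,
                    "se_all": self.se_all,
                    "indirect": self.indirect,
                    "se_indirect": self.se_indirect,
                    "direct": self.direct,
                    "proportion": self.proportion,
                    "proportion_ci_low": self.proportion_ci[0],
                    "proportion_ci_high": self.proportion_ci[1],
                    "pval_indirect": self.pval_indirect,
                    "flags": ";".join(self.flags),
                }
            ]
        )


@dataclass
class ScreenCriteria:
    """Selection rules for many-exposure screening."""

    ivw_p_max: float = 0.01
    pleiotropy_p_min: float = 0.05
    require_direction_consistency: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.ivw_p_max < 1) or not (0 <= self.pleiotropy_p_min < 1):
            raise ValidationError("screen thresholds must lie in (0, 1)")


@dataclass
class ScreenResult:
    table: pd.DataFrame  # one row per exposure with pass flags
    selected: list[str]
    panels: dict[str, MRPanel]
    reverse: dict[str, tuple[MRPanel | None, bool, str]] = field(default_factory=dict)
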