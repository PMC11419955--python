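"""Reading, writing, and harmonizing GWAS summary-statistics tables.

Tables are tab-separated with a header.  Two built-in dialects map column
names onto the canonical schema: ``generic`` (the names this package writes)
and ``gwascat`` (GWAS-Catalog harmonized-file naming, ``hm_rsid`` etc.).  A
custom mapping may be supplied instead of a dialect name.

Harmonization aligns an outcome table onto the exposure's effect alleles:
swapped alleles flip the outcome beta sign and frequency, complementary-strand
records are strand-flipped first, and palindromic (A/T, C/G) variants are
either frequency-oriented or dropped depending on policy.
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import SUMSTAT_COLUMNS, HarmonizedSet, LoadReport, SummaryStats
from .errors import EmptyInputError, NoOverlapError, ValidationError

#: built-in column-name dialects (canonical name -> file column name)
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {c: c for c in SUMSTAT_COLUMNS},
    "gwascat": {
        "snp": "hm_rsid",
        "chrom": "hm_chrom",
        "pos": "hm_pos",
        "effect_allele": "hm_effect_allele",
        "other_allele": "hm_other_allele",
        "eaf": "hm_effect_allele_frequency",
        "beta": "hm_beta",
        "se": "standard_error",
        "pval": "p_value",
        "n": "n",
    },
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _resolve_dialect(dialect: str | Mapping[str, str]) -> dict[str, str]:
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError:
            raise ValidationError(
                f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}"
            ) from None
    return {c: dialect.get(c, c) for c in SUMSTAT_COLUMNS}


def read_summary_stats(
    path,
    dialect: str | Mapping[str, str] = "generic",
    trait_id: str | None = None,
) -> tuple[SummaryStats, LoadReport]:
    """Read one trait's summary statistics from a TSV file.

    Rows violating record invariants (se <= 0, p outside (0, 1], non-SNP
    alleles, ...) are dropped and tallied in the returned :class:`LoadReport`.

    Raises
    ------
    EmptyInputError
        If no valid rows remain.
    ValidationError
        If a mandatory column cannot be resolved through the dialect.
    """
    mapping = _resolve_dialect(dialect)
    raw = pd.read_csv(path, sep="\t", dtype={mapping["snp"]: str})
    missing = [
        canon
        for canon in ("snp", "effect_allele", "other_allele", "beta", "se", "pval")
        if mapping[canon] not in raw.columns
    ]
    if missing:
        raise ValidationError(
            f"{path}: cannot resolve mandatory columns {missing} "
            f"via dialect mapping {mapping}"
        )
    df = pd.DataFrame()
    for canon in SUMSTAT_COLUMNS:
        src = mapping[canon]
        df[canon] = raw[src] if src in raw.columns else np.nan
    for allele_col in ("effect_allele", "other_allele"):
        df[allele_col] = df[allele_col].astype(str).str.upper()
    if trait_id is None:
        trait_id = str(path)
    stats, report = SummaryStats.clean(trait_id, df)
    if len(stats) == 0:
        raise EmptyInputError(f"{path}: no valid summary-statistics rows")
    return stats, report


def write_summary_stats(stats: SummaryStats, path) -> None:
    """Write a table in the generic dialect (UTF-8, tab-separated)."""
    stats.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def is_palindromic(ea: str, oa: str) -> bool:
    """A/T or C/G allele pairs: strand is unresolvable from alleles alone."""
    return _COMPLEMENT.get(ea) == oa


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    palindrome_policy: str = "infer_by_eaf",
    ambiguity_maf: float = 0.42,
) -> HarmonizedSet:
    """Align outcome effects onto the exposure's effect alleles.

    For each shared variant: matching alleles are kept as-is; swapped alleles
    (outcome effect allele equals exposure other allele and vice versa) negate
    the outcome beta and replace its frequency with 1-eaf; complementary-strand
    representations are strand-flipped first and then handled the same way.
    Palindromic variants are oriented by effect-allele frequency under
    ``infer_by_eaf`` — and dropped as ambiguous when either study's minor
    allele frequency exceeds ``ambiguity_maf`` or a frequency is missing — or
    all dropped under ``drop_all``.  Unresolvable allele sets are dropped.

    Raises
    ------
    NoOverlapError
        If the tables share no variant identifiers.
    """
    if palindrome_policy not in ("infer_by_eaf", "drop_all"):
        raise ValidationError(f"unknown palindrome policy {palindrome_policy!r}")
    exp = exposure.df.set_index("snp", drop=False)
    out = outcome.df.set_index("snp", drop=False)
    shared = [s for s in exposure.df["snp"] if s in out.index]
    if not shared:
        raise NoOverlapError(
            f"no shared variants between {exposure.trait_id} and {outcome.trait_id}"
        )

    kept_ids: list[str] = []
    bx, se_x, by, se_y, eaf = [], [], [], [], []
    dropped: Counter = Counter()
    dropped_snps: dict[str, str] = {}

    def drop(snp: str, reason: str) -> None:
        dropped[reason] += 1
        dropped_snps[snp] = reason

    for snp in shared:
        ex = exp.loc[snp]
        ou = out.loc[snp]
        ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
        ea_y, oa_y = ou["effect_allele"], ou["other_allele"]
        b_y, f_y = float(ou["beta"]), ou["eaf"]

        if is_palindromic(ea_x, oa_x):
            if palindrome_policy == "drop_all":
                drop(snp, "palindromic")
                continue
            # label alignment first (labels alone cannot resolve strand)
            if (ea_y, oa_y) == (ea_x, oa_x):
                pass
            elif (ea_y, oa_y) == (oa_x, ea_x):
                b_y = -b_y
                f_y = 1 - f_y if pd.notna(f_y) else f_y
            else:
                drop(snp, "incompatible_alleles")
                continue
            f_x = ex["eaf"]
            if pd.isna(f_x) or pd.isna(f_y):
                drop(snp, "palindromic_missing_eaf")
                continue
            if min(f_x, 1 - f_x) > ambiguity_maf or min(f_y, 1 - f_y) > ambiguity_maf:
                drop(snp, "palindromic_ambiguous")
                continue
            if (f_x < 0.5) != (f_y < 0.5):
                # frequencies disagree: the studies report opposite strands
                b_y = -b_y
                f_y = 1 - f_y
        else:
            if (ea_y, oa_y) == (ea_x, oa_x):
                pass
            elif (ea_y, oa_y) == (oa_x, ea_x):
                b_y = -b_y
                f_y = 1 - f_y if pd.notna(f_y) else f_y
            else:
                ea_yc = _COMPLEMENT.get(ea_y)
                oa_yc = _COMPLEMENT.get(oa_y)
                if (ea_yc, oa_yc) == (ea_x, oa_x):
                    pass
                elif (ea_yc, oa_yc) == (oa_x, ea_x):
                    b_y = -b_y
                    f_y = 1 - f_y if pd.notna(f_y) else f_y
                else:
                    drop(snp, "incompatible_alleles")
                    continue

        kept_ids.append(snp)
        bx.append(float(ex["beta"]))
        se_x.append(float(ex["se"]))
        by.append(b_y)
        se_y.append(float(ou["se"]))
        f_x = ex["eaf"]
        eaf.append(float(f_x) if pd.notna(f_x) else (float(f_y) if pd.notna(f_y) else np.nan))

    if not kept_ids:
        raise EmptyInputError(
            f"harmonization dropped every shared variant "
            f"({dict(dropped)}) for {exposure.trait_id} vs {outcome.trait_id}"
        )
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        snp_ids=kept_ids,
        bx=bx,
        se_x=se_x,
        by=by,
        se_y=se_y,
        eaf=eaf,
        n_dropped=dropped,
        dropped_snps=dropped_snps,
    )
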