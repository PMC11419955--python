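"""Synthetic GWAS summary statistics with known causal structure.

The generator realizes the mediation diagram X -> M -> Y plus a direct
X -> Y path: per-SNP true effects on the exposure follow a spike-and-slab
architecture (a fraction of SNPs causal), the mediator inherits theta_xm
times the exposure effects plus its own instrument effects, and the binary
outcome (log-odds scale) receives (theta_xm*theta_my + theta_xy_direct)
times the exposure effects, theta_my times the mediator-specific effects,
optional per-SNP pleiotropy, and optional outcome-specific effects that can
feed back on the exposure (theta_yx) for reverse-causation positive controls.

Observed betas are the true marginal effects plus sampling noise with the
standard GWAS standard errors se = 1/sqrt(2 p (1-p) n) for a
variance-standardized quantitative trait, using the effective sample size
n_eff = 4 / (1/cases + 1/controls) for the case-control outcome.  LD is
emulated as a block-diagonal r^2 matrix over consecutive SNPs; block members
are placed close together so clumping windows behave realistically.

Default sample sizes mirror the emulated study: a lipid exposure cohort of
771, a metabolite mediator cohort of 8,299, and a melanoma outcome with 98
cases and 218,694 controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import LDMatrix, SummaryStats
from .errors import ValidationError

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_study",
    "simulate_screening_study",
    "study_shaped_fixture",
    "STUDY_FIXTURE_SEED",
]

# non-palindromic allele pairs only, so harmonization never drops by ambiguity
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


@dataclass
class SimulationConfig:
    """Causal diagram, genetic architecture, and sample sizes to realize."""

    n_snps: int = 200
    n_exposure: int = 771
    n_mediator: int = 8299
    n_outcome_cases: int = 98
    n_outcome_controls: int = 218_694
    theta_xm: float = 0.2
    theta_my: float = 0.6
    theta_xy_direct: float = 0.1
    theta_yx: float = 0.0
    theta_mx: float = 0.0
    pleiotropy_sd: float = 0.0
    directional_pleiotropy_mean: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_blocks: Sequence[tuple[int, float]] = field(default_factory=list)
    exposure_causal_fraction: float = 0.1
    mediator_causal_fraction: float = 0.1
    outcome_causal_fraction: float = 0.0
    exposure_effect_sd: float = 0.35
    mediator_effect_sd: float = 0.12
    outcome_effect_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_snps", "n_exposure", "n_mediator",
                     "n_outcome_cases", "n_outcome_controls"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValidationError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if self.pleiotropy_sd < 0:
            raise ValidationError("pleiotropy_sd must be non-negative")
        for frac in (self.exposure_causal_fraction, self.mediator_causal_fraction,
                     self.outcome_causal_fraction):
            if not (0 <= frac <= 1):
                raise ValidationError("causal fractions must lie in [0, 1]")

    @property
    def n_eff_outcome(self) -> float:
        """Effective sample size for case-control log-odds statistics."""
        return 4.0 / (1.0 / self.n_outcome_cases + 1.0 / self.n_outcome_controls)

    @property
    def true_total(self) -> float:
        return self.theta_xm * self.theta_my + self.theta_xy_direct

    @property
    def true_proportion(self) -> float:
        if self.true_total == 0:
            return float("nan")
        return self.theta_xm * self.theta_my / self.true_total


@dataclass
class SyntheticStudy:
    """One simulated triplet of linked summary-statistics tables."""

    exposure: SummaryStats
    mediator: SummaryStats
    outcome: SummaryStats
    ld: LDMatrix
    truth: dict

    def tables(self) -> dict[str, SummaryStats]:
        return {"exposure": self.exposure, "mediator": self.mediator,
                "outcome": self.outcome}


def _positions(n_snps: int, blocks: Sequence[tuple[int, float]], rng) -> tuple:
    """Assign chromosomes/positions; LD-block members sit 10 kb apart."""
    chrom = np.empty(n_snps, dtype=object)
    pos = np.empty(n_snps, dtype=int)
    block_id = np.full(n_snps, -1, dtype=int)
    idx = 0
    b = 0
    for size, _r2 in blocks:
        for j in range(size):
            if idx >= n_snps:
                break
            block_id[idx] = b
            idx += 1
        b += 1
    cur_chrom, cur_pos = 1, 1_000_000
    i = 0
    while i < n_snps:
        if block_id[i] >= 0:
            this_block = block_id[i]
            while i < n_snps and block_id[i] == this_block:
                chrom[i] = str(cur_chrom)
                pos[i] = cur_pos
                cur_pos += 10_000
                i += 1
        else:
            chrom[i] = str(cur_chrom)
            pos[i] = cur_pos
            i += 1
        cur_pos += 20_000_000  # next variant/block well outside any clump window
        if cur_pos > 240_000_000:
            cur_chrom += 1
            cur_pos = 1_000_000
    return chrom, pos, block_id


def _ld_matrix(snp_ids, block_id, blocks) -> LDMatrix:
    k = len(snp_ids)
    r2 = np.eye(k)
    for b, (_size, within_r2) in enumerate(blocks):
        members = np.where(block_id == b)[0]
        for i in members:
            for j in members:
                if i != j:
                    r2[i, j] = within_r2
    return LDMatrix(snp_ids, r2)


def _table(trait_id, snp_ids, chrom, pos, ea, oa, eaf, beta_true, se, n, rng,
           swap_fraction=0.0) -> SummaryStats:
    beta = beta_true + rng.normal(0.0, se)
    pval = 2 * sps.norm.sf(np.abs(beta) / se)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    ea = np.asarray(ea, dtype=object).copy()
    oa = np.asarray(oa, dtype=object).copy()
    eaf = np.asarray(eaf, dtype=float).copy()
    beta = np.asarray(beta, dtype=float)
    if swap_fraction > 0:
        # report some records with the alleles in the opposite representation
        swap = rng.random(len(snp_ids)) < swap_fraction
        ea[swap], oa[swap] = oa[swap].copy(), ea[swap].copy()
        eaf[swap] = 1 - eaf[swap]
        beta = beta.copy()
        beta[swap] = -beta[swap]
    df = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": int(round(n)),
        }
    )
    return SummaryStats(trait_id, df, validate=False)


def _spike_slab(rng, n, fraction, sd, exclude=None) -> np.ndarray:
    """Spike-and-slab effects; ``exclude`` masks SNPs kept in the spike.

    Trait-specific supports are disjoint: a SNP already causal for an
    upstream trait is excluded, so each trait's instruments act on other
    traits only through the modelled causal paths (any residual overlap in
    real data is what the pleiotropy terms emulate).
    """
    causal = rng.random(n) < fraction
    if exclude is not None:
        causal &= ~exclude
    effects = np.zeros(n)
    effects[causal] = rng.normal(0.0, sd, size=int(causal.sum()))
    return effects


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate one exposure/mediator/outcome triplet; fully seed-determined."""
    rng = np.random.default_rng(config.seed)
    k = config.n_snps
    snp_ids = [f"rs{j + 1:07d}" for j in range(k)]
    chrom, pos, block_id = _positions(k, config.ld_blocks, rng)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    eaf = rng.uniform(config.maf_range[0], config.maf_range[1], size=k)

    a = _spike_slab(rng, k, config.exposure_causal_fraction, config.exposure_effect_sd)
    g = _spike_slab(rng, k, config.mediator_causal_fraction, config.mediator_effect_sd,
                    exclude=a != 0)
    d = _spike_slab(rng, k, config.outcome_causal_fraction, config.outcome_effect_sd,
                    exclude=(a != 0) | (g != 0))
    alpha = (
        rng.normal(config.directional_pleiotropy_mean, config.pleiotropy_sd, size=k)
        if (config.pleiotropy_sd > 0 or config.directional_pleiotropy_mean != 0)
        else np.zeros(k)
    )

    bx_true = a + config.theta_yx * d + config.theta_mx * g
    bm_true = g + config.theta_xm * bx_true
    by_true = d + config.theta_my * g + config.true_total * bx_true + alpha

    var_term = 2 * eaf * (1 - eaf)
    se_x = 1.0 / np.sqrt(var_term * config.n_exposure)
    se_m = 1.0 / np.sqrt(var_term * config.n_mediator)
    se_y = 1.0 / np.sqrt(var_term * config.n_eff_outcome)

    exposure = _table("exposure", snp_ids, chrom, pos, ea, oa, eaf, bx_true,
                      se_x, config.n_exposure, rng)
    mediator = _table("mediator", snp_ids, chrom, pos, ea, oa, eaf, bm_true,
                      se_m, config.n_mediator, rng, swap_fraction=0.5)
    n_out = config.n_outcome_cases + config.n_outcome_controls
    outcome = _table("outcome", snp_ids, chrom, pos, ea, oa, eaf, by_true,
                     se_y, n_out, rng, swap_fraction=0.5)
    ld = _ld_matrix(snp_ids, block_id, config.ld_blocks)
    truth = {
        "config": config,
        "true_total": config.true_total,
        "true_proportion": config.true_proportion,
        "bx_true": bx_true,
        "bm_true": bm_true,
        "by_true": by_true,
    }
    return SyntheticStudy(exposure, mediator, outcome, ld, truth)


def simulate_screening_study(
    config: SimulationConfig,
    n_exposures: int = 5,
    n_mediators: int = 3,
) -> dict:
    """A multi-trait screening study sharing one SNP panel and outcome.

    Exposure 1 and mediator 1 follow the causal diagram in ``config``; the
    remaining exposures and mediators have their own instruments but no
    effect on the outcome (screening nulls).
    """
    base = simulate_study(config)
    rng = np.random.default_rng(config.seed + 1_000_003)
    k = config.n_snps
    df0 = base.exposure.df
    exposures = {"exposure_1": base.exposure}
    mediators = {"mediator_1": base.mediator} if n_mediators >= 1 else {}
    var_term = 2 * df0["eaf"].to_numpy() * (1 - df0["eaf"].to_numpy())
    se_x = 1.0 / np.sqrt(var_term * config.n_exposure)
    se_m = 1.0 / np.sqrt(var_term * config.n_mediator)
    common = dict(
        snp_ids=df0["snp"].tolist(), chrom=df0["chrom"].to_numpy(),
        pos=df0["pos"].to_numpy(), ea=df0["effect_allele"].to_numpy(),
        oa=df0["other_allele"].to_numpy(), eaf=df0["eaf"].to_numpy(),
    )
    for i in range(2, n_exposures + 1):
        eff = _spike_slab(rng, k, config.exposure_causal_fraction,
                          config.exposure_effect_sd)
        exposures[f"exposure_{i}"] = _table(
            f"exposure_{i}", se=se_x, beta_true=eff, n=config.n_exposure,
            rng=rng, **common)
    for i in range(2, n_mediators + 1):
        eff = _spike_slab(rng, k, config.mediator_causal_fraction,
                          config.mediator_effect_sd)
        mediators[f"mediator_{i}"] = _table(
            f"mediator_{i}", se=se_m, beta_true=eff, n=config.n_mediator,
            rng=rng, **common)
    exposures["exposure_1"].trait_id = "exposure_1"
    if mediators:
        mediators["mediator_1"].trait_id = "mediator_1"
    return {
        "exposures": exposures,
        "mediators": mediators,
        "outcome": base.outcome,
        "ld": base.ld,
        "truth": base.truth,
    }


#: design seed of the bundled integration fixture
STUDY_FIXTURE_SEED = 305


def study_fixture_config(seed: int = STUDY_FIXTURE_SEED) -> SimulationConfig:
    """Configuration whose true odds ratios match the emulated study's
    headline estimates (1.059 exposure->mediator, 4.295 mediator->outcome,
    1.962 exposure->outcome) and whose architecture yields instrument counts
    near 28 (exposure) and 18 (mediator) under the default selection
    pipeline."""
    theta_xm = float(np.log(1.059))
    theta_my = float(np.log(4.295))
    theta_xy_direct = float(np.log(1.962)) - theta_xm * theta_my
    return SimulationConfig(
        n_snps=320,
        theta_xm=theta_xm,
        theta_my=theta_my,
        theta_xy_direct=theta_xy_direct,
        exposure_causal_fraction=0.15,
        mediator_causal_fraction=0.12,
        exposure_effect_sd=0.50,
        mediator_effect_sd=0.15,
        ld_blocks=[(3, 0.8), (2, 0.5)],
        seed=seed,
    )


def study_shaped_fixture() -> SyntheticStudy:
    """The fixed-seed integration fixture shaped like the emulated study."""
    return simulate_study(study_fixture_config())
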