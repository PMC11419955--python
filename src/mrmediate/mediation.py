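"""Two-step MR mediation decomposition.

Given three IVW estimates — exposure on mediator (beta1), mediator on outcome
(beta2), and exposure on outcome (beta_all, the total effect) — the indirect
(mediated) effect is the product beta1*beta2, the direct effect is the total
minus the indirect, and the proportion mediated is indirect / beta_all.  The
indirect-effect standard error uses the delta method for a product of
independent coefficients, sqrt(beta1^2 se2^2 + beta2^2 se1^2); the proportion
CI propagates it with beta_all treated as fixed (a full delta method that
also propagates se_all is available via ``proportion_ci_method="full"``).

Validity requires no causal effect of the mediator back on the exposure; the
pipeline checks this by reverse MR and flags, rather than rejects, failures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .datatypes import LDMatrix, MediationResult, MRPanel, SummaryStats
from .errors import DegenerateInputError, EmptyInputError, MRError

__all__ = ["two_step", "mediation_pipeline", "MRSettings", "run_mr"]


def two_step(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    beta_all: float,
    se_all: float,
    proportion_ci_method: str = "fixed_total",
) -> MediationResult:
    """Product-of-coefficients mediation decomposition with delta-method SE.

    Raises :class:`DegenerateInputError` when beta_all = 0 (the proportion is
    undefined).  When the indirect effect and the total effect disagree in
    sign the result carries an ``inconsistent_mediation`` flag and the
    proportion may fall outside [0, 1].
    """
    for name, se in (("se1", se1), ("se2", se2), ("se_all", se_all)):
        if not (se > 0):
            raise ValueError(f"{name} must be positive, got {se}")
    if beta_all == 0:
        raise DegenerateInputError("proportion mediated undefined for beta_all = 0")
    indirect = beta1 * beta2
    se_indirect = math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    direct = beta_all - indirect
    proportion = indirect / beta_all
    if proportion_ci_method == "fixed_total":
        se_prop = se_indirect / abs(beta_all)
    elif proportion_ci_method == "full":
        # first-order delta method on the ratio indirect / beta_all
        se_prop = abs(proportion) * math.sqrt(
            (se_indirect / indirect) ** 2 + (se_all / beta_all) ** 2
        ) if indirect != 0 else se_indirect / abs(beta_all)
    else:
        raise ValueError(f"unknown proportion CI method {proportion_ci_method!r}")
    ci = (proportion - 1.96 * se_prop, proportion + 1.96 * se_prop)
    if se_indirect == 0:
        pval = 1.0 if indirect == 0 else 0.0
    else:
        pval = float(2 * sps.norm.sf(abs(indirect) / se_indirect))
    flags = []
    if indirect != 0 and (indirect > 0) != (beta_all > 0):
        flags.append("inconsistent_mediation")
    return MediationResult(
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        beta_all=beta_all,
        se_all=se_all,
        indirect=indirect,
        se_indirect=se_indirect,
        direct=direct,
        proportion=proportion,
        proportion_ci=ci,
        pval_indirect=pval,
        flags=flags,
    )


@dataclass
class MRSettings:
    """Thresholds and estimator settings for one full MR analysis."""

    p_threshold: float = 1e-5
    window_kb: float = 10000.0
    r2_max: float = 0.001
    maf_min: float = 0.01
    f_min: float = 10.0
    palindrome_policy: str = "infer_by_eaf"
    ambiguity_maf: float = 0.42
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    phi: float = 1.0
    seed: int = 0
    reverse_p_min: float = 0.05

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def run_mr(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix,
    settings: MRSettings | None = None,
    full_panel: bool = True,
):
    """One complete MR analysis: selection, harmonization, estimation.

    Returns (InstrumentSet, MRPanel).  Instruments are selected from the
    exposure GWAS (p screen, clumping, MAF filter), harmonized with the
    outcome, and filtered for weak instruments before estimation.
    """
    from . import estimators, gwas_io, instruments

    if settings is None:
        settings = MRSettings()
    cand = instruments.select_candidates(exposure, settings.p_threshold)
    cand = instruments.clump(cand, ld, r2_max=settings.r2_max,
                             window_kb=settings.window_kb)
    cand = instruments.maf_filter(cand, maf_min=settings.maf_min)
    if len(cand) == 0:
        raise EmptyInputError(f"{exposure.trait_id}: no candidates after MAF filter")
    h = gwas_io.harmonize(
        cand, outcome,
        palindrome_policy=settings.palindrome_policy,
        ambiguity_maf=settings.ambiguity_maf,
    )
    n_exp = exposure.sample_size()
    if n_exp is None:
        raise ValueError(f"{exposure.trait_id}: sample size required for F filter")
    iv = instruments.build_instrument_set(h, exposure_n=n_exp, f_min=settings.f_min)
    panel_settings = estimators.PanelSettings(
        ivw_model=settings.ivw_model,
        n_boot=settings.n_boot if full_panel else 0,
        seed=settings.seed,
        phi=settings.phi,
    )
    if full_panel:
        panel = estimators.run_panel(iv.harmonized, panel_settings)
    else:
        est = estimators.ivw(iv.harmonized, model=settings.ivw_model)
        panel = MRPanel(h.exposure_id, h.outcome_id, {est.method: est})
    return iv, panel


def mediation_pipeline(
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix,
    settings: MRSettings | None = None,
) -> tuple[MediationResult, Mapping[str, MRPanel]]:
    """Full two-step mediation analysis from three summary-statistics tables.

    Runs three IVW analyses — exposure on mediator (beta1), mediator on
    outcome (beta2), exposure on outcome (beta_all) — decomposes via
    :func:`two_step`, and checks the prerequisite that the mediator has no
    causal effect back on the exposure (reverse MR IVW p above the
    threshold); a failed or untestable prerequisite flags the result rather
    than raising.

    Returns the :class:`MediationResult` and the dict of component panels
    (keys ``xm``, ``my``, ``xy``, and ``reverse_mx`` when testable).
    """
    if settings is None:
        settings = MRSettings()
    _, panel_xm = run_mr(exposure, mediator, ld, settings, full_panel=False)
    _, panel_my = run_mr(mediator, outcome, ld, settings, full_panel=False)
    _, panel_xy = run_mr(exposure, outcome, ld, settings, full_panel=False)
    panels: dict[str, MRPanel] = {"xm": panel_xm, "my": panel_my, "xy": panel_xy}
    flags: list[str] = []
    try:
        _, panel_rev = run_mr(mediator, exposure, ld, settings, full_panel=False)
        panels["reverse_mx"] = panel_rev
        rev_p = panel_rev.ivw().pval
        if rev_p < settings.reverse_p_min:
            flags.append("mediator_causes_exposure")
    except (EmptyInputError, MRError):
        flags.append("reverse_mr_untestable")

    e1, e2, eall = panel_xm.ivw(), panel_my.ivw(), panel_xy.ivw()
    result = two_step(e1.beta, e1.se, e2.beta, e2.se, eall.beta, eall.se)
    result.flags.extend(flags)
    return result, panels
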