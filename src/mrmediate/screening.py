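"""Many-exposure screening, reverse-MR gating, and study orchestration.

The screening rules mirror the emulated study's design: an exposure is
carried forward when its IVW p-value is below the threshold (0.01 for the
lipid-style screen, 0.001 for the metabolite-style screen), its
Egger-intercept pleiotropy p-value is above 0.05, and all available methods'
odds ratios point the same way.  Selected exposures must additionally pass a
reverse-MR gate (outcome-as-exposure IVW p >= 0.05) before mediation is
attempted.  No multiple-testing correction is applied in selection (the
emulated design uses raw thresholds); an FDR column is emitted for
transparency only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .datatypes import (
    LDMatrix,
    MRPanel,
    ScreenCriteria,
    ScreenResult,
    SummaryStats,
)
from .errors import EmptyInputError, MRError
from .mediation import MRSettings, mediation_pipeline, run_mr

__all__ = ["direction_consistent", "screen_exposures", "reverse_mr", "run_study"]


def direction_consistent(panel: MRPanel) -> tuple[bool, list[str]]:
    """True iff every estimated method's effect shares one sign.

    A beta of exactly zero counts as inconsistent.  A panel with fewer than
    two methods is vacuously consistent but flagged low-information.
    """
    betas = [est.beta for est in panel.estimates.values()]
    flags: list[str] = []
    if len(betas) < 2:
        flags.append("single_method")
        return True, flags
    if any(b == 0 for b in betas):
        return False, flags
    signs = {b > 0 for b in betas}
    return len(signs) == 1, flags


def _fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported, never used to select)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def screen_exposures(
    panels: Mapping[str, MRPanel], criteria: ScreenCriteria
) -> ScreenResult:
    """Apply the IVW-p / pleiotropy-p / direction-consistency screen.

    Returns every panel with per-criterion pass flags plus the selected
    subset, ordered by ascending IVW p (ties by exposure id).
    """
    if not panels:
        raise EmptyInputError("no panels to screen")
    rows = []
    for exp_id, panel in panels.items():
        ivw_est = panel.ivw()
        ivw_p = ivw_est.pval if ivw_est is not None else np.nan
        pleio_p = panel.pleiotropy.pval if panel.pleiotropy is not None else np.nan
        pass_ivw = bool(ivw_p < criteria.ivw_p_max)
        # a missing pleiotropy test (nsnp < 3) cannot demonstrate pleiotropy
        pass_pleio = bool(np.isnan(pleio_p) or pleio_p > criteria.pleiotropy_p_min)
        consistent, dflags = direction_consistent(panel)
        pass_dir = consistent or not criteria.require_direction_consistency
        rows.append(
            {
                "exposure": exp_id,
                "outcome": panel.outcome_id,
                "nsnp": panel.nsnp,
                "ivw_beta": ivw_est.beta if ivw_est else np.nan,
                "ivw_or": ivw_est.or_ if ivw_est else np.nan,
                "ivw_p": ivw_p,
                "pleiotropy_p": pleio_p,
                "pass_ivw": pass_ivw,
                "pass_pleiotropy": pass_pleio,
                "direction_consistent": consistent,
                "pass_direction": bool(pass_dir),
                "selected": bool(pass_ivw and pass_pleio and pass_dir),
                "flags": ";".join(dflags),
            }
        )
    table = pd.DataFrame(rows)
    table["ivw_fdr"] = _fdr(table["ivw_p"].fillna(1.0).to_numpy())
    table = table.sort_values(["ivw_p", "exposure"], kind="mergesort").reset_index(
        drop=True
    )
    selected = table.loc[table["selected"], "exposure"].tolist()
    return ScreenResult(table=table, selected=selected, panels=dict(panels))


def reverse_mr(
    outcome_as_exposure: SummaryStats,
    exposure_as_outcome: SummaryStats,
    ld: LDMatrix,
    settings: MRSettings | None = None,
) -> tuple[MRPanel | None, bool, str]:
    """Reverse-direction MR gate.

    Instruments are selected for the original outcome trait and tested
    against the original exposure.  Passes (no reverse causation) when the
    reverse IVW p-value is at or above ``settings.reverse_p_min``.  When no
    instruments are derivable for the reversed exposure the gate passes with
    an ``untestable`` flag rather than silently.
    """
    if settings is None:
        settings = MRSettings()
    try:
        _, panel = run_mr(outcome_as_exposure, exposure_as_outcome, ld, settings)
    except (EmptyInputError, MRError) as exc:
        return None, True, f"untestable: {exc}"
    ivw_p = panel.ivw().pval
    passed = bool(ivw_p >= settings.reverse_p_min)
    return panel, passed, "" if passed else "reverse_causation"


@dataclass
class StudyConfig:
    """End-to-end study configuration.

    Data may be simulated (``simulate`` holds SimulationConfig fields) or
    loaded from generic-dialect TSVs (``exposure_files``/``mediator_files``/
    ``outcome_file``/``ld_file``).
    """

    settings: MRSettings
    ivw_p_exposure: float = 0.01
    ivw_p_mediator: float = 0.001
    pleiotropy_p_min: float = 0.05
    xm_p_max: float = 0.05
    simulate: dict | None = None
    n_sim_exposures: int = 5
    n_sim_mediators: int = 3
    exposure_files: list[str] | None = None
    mediator_files: list[str] | None = None
    outcome_file: str | None = None
    ld_file: str | None = None
    dialect: str = "generic"


def _load_study_data(config: StudyConfig) -> dict:
    from . import gwas_io
    from .simulate import SimulationConfig, simulate_screening_study

    if config.simulate is not None:
        sim_cfg = SimulationConfig(**config.simulate)
        return simulate_screening_study(
            sim_cfg,
            n_exposures=config.n_sim_exposures,
            n_mediators=config.n_sim_mediators,
        )
    exposures = {}
    for path in config.exposure_files or []:
        stats, _ = gwas_io.read_summary_stats(path, config.dialect,
                                              trait_id=Path(path).stem)
        exposures[stats.trait_id] = stats
    mediators = {}
    for path in config.mediator_files or []:
        stats, _ = gwas_io.read_summary_stats(path, config.dialect,
                                              trait_id=Path(path).stem)
        mediators[stats.trait_id] = stats
    if not exposures or config.outcome_file is None or config.ld_file is None:
        raise EmptyInputError("study config must name exposures, outcome, and LD")
    outcome, _ = gwas_io.read_summary_stats(config.outcome_file, config.dialect,
                                            trait_id=Path(config.outcome_file).stem)
    ld = LDMatrix.read(config.ld_file)
    return {"exposures": exposures, "mediators": mediators,
            "outcome": outcome, "ld": ld, "truth": None}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_study(config: StudyConfig, out_dir) -> dict:
    """Execute the full screening + mediation study and write TSV reports.

    Stages: screen exposures against the outcome; reverse-MR gate the
    selected exposures; screen mediator candidates against the outcome;
    estimate exposure -> mediator effects; decompose qualifying triplets by
    two-step mediation.  Per-exposure failures are collected in the error
    report and abort only that exposure's downstream stages.  With a fixed
    seed the written reports are byte-identical across reruns.
    """
    from . import diagnostics

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    settings = config.settings
    data = _load_study_data(config)
    exposures, mediators = data["exposures"], data["mediators"]
    outcome, ld = data["outcome"], data["ld"]

    errors: list[dict] = []
    panel_rows, het_rows, pleio_rows, loo_rows = [], [], [], []

    def record_panel(panel: MRPanel, h) -> None:
        panel_rows.append(panel.to_frame())
        for ref, het in panel.heterogeneity.items():
            het_rows.append(
                {"exposure": panel.exposure_id, "outcome": panel.outcome_id,
                 "reference": ref, "q": het.q, "df": het.df, "pval": het.pval}
            )
        if panel.pleiotropy is not None:
            pleio_rows.append(
                {"exposure": panel.exposure_id, "outcome": panel.outcome_id,
                 "egger_intercept": panel.pleiotropy.intercept,
                 "se": panel.pleiotropy.se, "pval": panel.pleiotropy.pval}
            )
        if h is not None and h.nsnp >= 3:
            loo = diagnostics.leave_one_out(h, model=settings.ivw_model)
            t = loo.table.copy()
            t.insert(0, "outcome", panel.outcome_id)
            t.insert(0, "exposure", panel.exposure_id)
            loo_rows.append(t)

    # stage 1: exposure screen against the outcome
    exp_panels: dict[str, MRPanel] = {}
    for exp_id, stats in sorted(exposures.items()):
        try:
            iv, panel = run_mr(stats, outcome, ld, settings)
            exp_panels[exp_id] = panel
            record_panel(panel, iv.harmonized)
        except MRError as exc:
            errors.append({"stage": "exposure_screen", "trait": exp_id,
                           "error": str(exc)})
    if not exp_panels:
        raise EmptyInputError("no exposure produced an MR panel")
    exp_criteria = ScreenCriteria(config.ivw_p_exposure, config.pleiotropy_p_min)
    exp_screen = screen_exposures(exp_panels, exp_criteria)
    _write_tsv(exp_screen.table, out / "screen_exposures.tsv")

    # stage 2: reverse-MR gate on selected exposures
    rev_rows = []
    gated: list[str] = []
    for exp_id in exp_screen.selected:
        panel, passed, flag = reverse_mr(outcome, exposures[exp_id], ld, settings)
        rev_p = panel.ivw().pval if panel is not None else np.nan
        rev_rows.append({"exposure": exp_id, "reverse_ivw_p": rev_p,
                         "passed": passed, "flag": flag})
        if passed:
            gated.append(exp_id)
    _write_tsv(pd.DataFrame(rev_rows,
                            columns=["exposure", "reverse_ivw_p", "passed", "flag"]),
               out / "reverse_mr.tsv")

    # stage 3: mediator screen against the outcome
    med_panels: dict[str, MRPanel] = {}
    for med_id, stats in sorted(mediators.items()):
        try:
            iv, panel = run_mr(stats, outcome, ld, settings)
            med_panels[med_id] = panel
            record_panel(panel, iv.harmonized)
        except MRError as exc:
            errors.append({"stage": "mediator_screen", "trait": med_id,
                           "error": str(exc)})
    med_selected: list[str] = []
    if med_panels:
        med_criteria = ScreenCriteria(config.ivw_p_mediator, config.pleiotropy_p_min)
        med_screen = screen_exposures(med_panels, med_criteria)
        _write_tsv(med_screen.table, out / "screen_mediators.tsv")
        med_selected = med_screen.selected

    # stage 4: exposure -> mediator MR and mediation decomposition
    med_rows = []
    for exp_id in gated:
        for med_id in med_selected:
            try:
                _, panel_xm = run_mr(exposures[exp_id], mediators[med_id],
                                     ld, settings)
                record_panel(panel_xm, None)
                if panel_xm.ivw().pval >= config.xm_p_max:
                    continue
                result, _panels = mediation_pipeline(
                    exposures[exp_id], mediators[med_id], outcome, ld, settings
                )
                row = result.to_frame().iloc[0].to_dict()
                row = {"exposure": exp_id, "mediator": med_id,
                       "outcome": outcome.trait_id, **row}
                med_rows.append(row)
            except MRError as exc:
                errors.append({"stage": "mediation", "trait": f"{exp_id}/{med_id}",
                               "error": str(exc)})
    if med_rows:
        mediation_table = pd.DataFrame(med_rows)
    else:
        mediation_table = pd.DataFrame(
            columns=["exposure", "mediator", "outcome", "beta1", "se1", "beta2",
                     "se2", "beta_all", "se_all", "indirect", "se_indirect",
                     "direct", "proportion", "proportion_ci_low",
                     "proportion_ci_high", "pval_indirect", "flags"]
        )
    _write_tsv(mediation_table, out / "mediation.tsv")

    _write_tsv(pd.concat(panel_rows, ignore_index=True), out / "mr_estimates.tsv")
    _write_tsv(pd.DataFrame(het_rows), out / "heterogeneity.tsv")
    _write_tsv(pd.DataFrame(pleio_rows), out / "pleiotropy.tsv")
    if loo_rows:
        _write_tsv(pd.concat(loo_rows, ignore_index=True), out / "leave_one_out.tsv")
    _write_tsv(pd.DataFrame(errors, columns=["stage", "trait", "error"]),
               out / "errors.tsv")

    log = {
        "package": "mrmediate",
        "version": __version__,
        "seed": settings.seed,
        "settings": settings.as_dict(),
        "thresholds": {
            "ivw_p_exposure": config.ivw_p_exposure,
            "ivw_p_mediator": config.ivw_p_mediator,
            "pleiotropy_p_min": config.pleiotropy_p_min,
            "xm_p_max": config.xm_p_max,
        },
        "n_exposures": len(exposures),
        "n_mediators": len(mediators),
        "selected_exposures": exp_screen.selected,
        "gated_exposures": gated,
        "selected_mediators": med_selected,
        "n_mediation_results": len(med_rows),
        "no_mediation_attempted": len(mediators) == 0,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return {
        "exposure_screen": exp_screen,
        "gated_exposures": gated,
        "mediator_selected": med_selected,
        "mediation": mediation_table,
        "errors": errors,
        "log": log,
    }
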