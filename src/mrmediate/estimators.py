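"""Causal-effect estimators for two-sample MR.

All estimators consume a :class:`HarmonizedSet` and return an
:class:`MREstimate` on the log scale (log odds ratio for binary outcomes).
Five methods are provided — inverse-variance weighted (IVW), MR-Egger,
weighted median, and the simple and weighted mode estimators — plus the
single-SNP Wald ratio.  IVW defaults to the multiplicative random-effects
model: the fixed-effect standard error is inflated by sqrt(max(Q/(k-1), 1))
under heterogeneity but never deflated.  MR-Egger p-values use a t
distribution on k-2 degrees of freedom; all others use the normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .datatypes import (
    HarmonizedSet,
    HeterogeneityResult,
    MREstimate,
    MRPanel,
    PleiotropyResult,
)
from .errors import DegenerateInputError, InsufficientInstrumentsError

__all__ = [
    "PanelSettings",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimate",
    "run_panel",
]


@dataclass
class PanelSettings:
    """Estimator settings shared across a panel run."""

    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    seed: int = 0
    phi: float = 1.0


def _normal_p(beta: float, se: float) -> float:
    if se == 0:
        return 0.0 if beta != 0 else 1.0
    return float(2 * sps.norm.sf(abs(beta) / se))


def wald_ratio(bx: float, se_x: float, by: float, se_y: float) -> MREstimate:
    """Single-SNP causal estimate by/bx with first-order SE se_y/|bx|."""
    if bx == 0:
        raise DegenerateInputError("Wald ratio undefined for bx = 0")
    beta = by / bx
    se = se_y / abs(bx)
    return MREstimate("Wald", float(beta), float(se), _normal_p(beta, se), nsnp=1)


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted least squares of the outcome effects on the exposure effects
    through the origin, weights 1/se_y^2.  The ``fixed`` model uses the
    analytic WLS standard error; ``multiplicative_random`` scales it by
    sqrt(max(Q/(k-1), 1)) where Q is Cochran's Q.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    k = h.nsnp
    if k == 1:
        est = wald_ratio(h.bx[0], h.se_x[0], h.by[0], h.se_y[0])
        est.method = "IVW"
        return est
    w = 1.0 / h.se_y**2
    denom = float(np.sum(w * h.bx**2))
    if denom == 0:
        raise DegenerateInputError("IVW undefined: all exposure effects are zero")
    beta = float(np.sum(w * h.bx * h.by)) / denom
    se = np.sqrt(1.0 / denom)
    if model == "multiplicative_random":
        q = float(np.sum(w * (h.by - beta * h.bx) ** 2))
        se *= np.sqrt(max(q / (k - 1), 1.0))
    return MREstimate("IVW", beta, float(se), _normal_p(beta, se), nsnp=k)


def mr_egger(h: HarmonizedSet) -> tuple[MREstimate, PleiotropyResult]:
    """MR-Egger regression: slope (causal effect) and intercept (pleiotropy).

    Each SNP is oriented so its exposure effect is non-negative, then the
    outcome effects are regressed on the exposure effects with a free
    intercept, weights 1/se_y^2.  Standard errors come from the weighted
    fit with residual variance floored at 1 (never deflated under
    underdispersion); p-values are two-sided t on k-2 df.
    """
    k = h.nsnp
    if k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {k}")
    sign = np.where(h.bx < 0, -1.0, 1.0)
    bx = h.bx * sign
    by = h.by * sign
    if np.allclose(bx, bx[0]):
        raise DegenerateInputError(
            "MR-Egger undefined: no spread in |exposure effects|"
        )
    w = 1.0 / h.se_y**2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    sigma = np.sqrt(fit.scale)
    adj = max(sigma, 1.0) / sigma  # floor residual sd at 1
    se_int, se_slope = fit.bse * adj
    a, b = fit.params
    p_slope = float(2 * sps.t.sf(abs(b) / se_slope, df=k - 2))
    p_int = float(2 * sps.t.sf(abs(a) / se_int, df=k - 2))
    est = MREstimate("MR-Egger", float(b), float(se_slope), p_slope, nsnp=k)
    pleio = PleiotropyResult(float(a), float(se_int), p_int)
    return est, pleio


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median over sorted ratios."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return float(r[0])
    below = int(np.searchsorted(s, 0.5, side="left")) - 1
    if below >= len(r) - 1:
        return float(r[-1])
    frac = (0.5 - s[below]) / (s[below + 1] - s[below])
    return float(r[below] + frac * (r[below + 1] - r[below]))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Weights are the inverse squared first-order SEs of the ratios,
    (bx/se_y)^2, normalized to sum to one.  The standard error is a
    parametric bootstrap: exposure and outcome effects are resampled from
    normals centred at the observed values, ratios recomputed, and the
    weighted median (with the observed weights) re-evaluated.
    """
    k = h.nsnp
    if k < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {k}")
    ratios = h.by / h.bx
    weights = (h.bx / h.se_y) ** 2
    beta = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(h.bx, h.se_x, size=(n_boot, k))
    by_b = rng.normal(h.by, h.se_y, size=(n_boot, k))
    boot = np.array(
        [_weighted_median_point(by_b[i] / bx_b[i], weights) for i in range(n_boot)]
    )
    se = float(boot.std(ddof=1))
    return MREstimate("weighted_median", beta, se, _normal_p(beta, se), nsnp=k)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    k = len(ratios)
    sd = ratios.std(ddof=1)
    iqr = np.subtract(*np.percentile(ratios, [75, 25]))
    return float(phi * 0.9 * min(sd, iqr / 1.349) * k ** (-0.2))


def _mode_point(
    ratios: np.ndarray, weights: np.ndarray, h_bw: float, n_grid: int = 1024
) -> float:
    """Argmax of the weighted Gaussian-kernel density over a fine grid."""
    grid = np.linspace(ratios.min(), ratios.max(), n_grid)
    grid = np.union1d(grid, ratios)
    z = (grid[:, None] - ratios[None, :]) / h_bw
    dens = np.exp(-0.5 * z**2) @ weights
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate: argmax of the kernel-smoothed ratio density.

    ``weighted=True`` weights each ratio by the inverse of its squared
    first-order SE; ``weighted=False`` is the simple mode.  The bandwidth is
    phi * 0.9 * min(sd, iqr/1.349) * k^(-1/5) over the ratios.  All ratios
    identical (zero bandwidth) returns the common ratio with se 0 and a flag.
    """
    k = h.nsnp
    if k < 3:
        raise InsufficientInstrumentsError(f"mode estimator needs >= 3 SNPs, got {k}")
    if phi <= 0:
        raise ValueError(f"phi must be positive, got {phi}")
    method = "weighted_mode" if weighted else "simple_mode"
    ratios = h.by / h.bx
    se_ratio = h.se_y / np.abs(h.bx)
    weights = 1.0 / se_ratio**2 if weighted else np.ones(k)
    weights = weights / weights.sum()
    h_bw = _mode_bandwidth(ratios, phi)
    if h_bw == 0 or np.allclose(ratios, ratios[0]):
        beta = float(ratios[0])
        return MREstimate(method, beta, 0.0, _normal_p(beta, 1e-300), nsnp=k,
                          flags=["degenerate_ratios"])
    beta = _mode_point(ratios, weights, h_bw)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        bx_b = rng.normal(h.bx, h.se_x)
        by_b = rng.normal(h.by, h.se_y)
        r_b = by_b / bx_b
        hb = _mode_bandwidth(r_b, phi)
        boot[i] = r_b[0] if hb == 0 else _mode_point(r_b, weights, hb, n_grid=256)
    se = float(boot.std(ddof=1))
    return MREstimate(method, beta, se, _normal_p(beta, se), nsnp=k)


def run_panel(h: HarmonizedSet, settings: PanelSettings | None = None) -> MRPanel:
    """Run every estimator the instrument count admits, plus diagnostics.

    nsnp = 1 yields only the Wald ratio; nsnp = 2 adds IVW; nsnp >= 3 yields
    the full five-method panel with heterogeneity (Cochran's Q under both the
    IVW and Egger references) and the Egger-intercept pleiotropy test.
    Methods that cannot run are recorded in ``skipped`` with a reason.
    """
    from . import diagnostics  # local import to avoid a cycle

    if settings is None:
        settings = PanelSettings()
    k = h.nsnp
    estimates: dict[str, MREstimate] = {}
    skipped: dict[str, str] = {}
    heterogeneity: dict[str, HeterogeneityResult] = {}
    pleiotropy: PleiotropyResult | None = None

    if k == 1:
        estimates["Wald"] = wald_ratio(h.bx[0], h.se_x[0], h.by[0], h.se_y[0])
        for m in ("IVW", "MR-Egger", "weighted_median", "simple_mode", "weighted_mode"):
            skipped[m] = "nsnp < minimum"
        return MRPanel(h.exposure_id, h.outcome_id, estimates, heterogeneity,
                       pleiotropy, skipped)

    estimates["IVW"] = ivw(h, model=settings.ivw_model)
    heterogeneity["ivw"] = diagnostics.cochran_q(h, reference="ivw")
    if k >= 3:
        try:
            egger_est, pleiotropy = mr_egger(h)
            estimates["MR-Egger"] = egger_est
            heterogeneity["egger"] = diagnostics.cochran_q(h, reference="egger")
        except DegenerateInputError as exc:
            skipped["MR-Egger"] = str(exc)
        estimates["weighted_median"] = weighted_median(
            h, n_boot=settings.n_boot, seed=settings.seed
        )
        estimates["simple_mode"] = mode_estimate(
            h, weighted=False, phi=settings.phi,
            n_boot=settings.n_boot, seed=settings.seed + 1,
        )
        estimates["weighted_mode"] = mode_estimate(
            h, weighted=True, phi=settings.phi,
            n_boot=settings.n_boot, seed=settings.seed + 2,
        )
    else:
        for m in ("MR-Egger", "weighted_median", "simple_mode", "weighted_mode"):
            skipped[m] = "nsnp < 3"
    return MRPanel(h.exposure_id, h.outcome_id, estimates, heterogeneity,
                   pleiotropy, skipped)
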