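"""Heterogeneity, pleiotropy, and sensitivity diagnostics.

Cochran's Q measures dispersion of the per-SNP Wald ratios around a reference
fit (IVW through the origin, or the Egger line); leave-one-out re-estimates
IVW with each instrument omitted; funnel/scatter tables carry the data behind
the standard MR displays.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import HarmonizedSet, HeterogeneityResult, LeaveOneOutResult, MRPanel
from .errors import InsufficientInstrumentsError

__all__ = ["cochran_q", "leave_one_out", "funnel_scatter_data"]


def cochran_q(h: HarmonizedSet, reference: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q around the IVW or MR-Egger fit.

    IVW reference: Q = sum_j w_j (r_j - beta)^2 on the ratio scale with
    first-order weights w_j = (bx_j / se_y_j)^2 (equivalently the weighted
    residual sum of squares of the origin-constrained fit), df = k-1.
    Egger reference: weighted residual sum of squares around the intercept
    fit, df = k-2.  The p-value is the upper chi-square tail.
    """
    from . import estimators  # local import to avoid a cycle

    k = h.nsnp
    if reference == "ivw":
        if k < 2:
            raise InsufficientInstrumentsError("Q (IVW) needs >= 2 SNPs")
        beta = estimators.ivw(h, model="fixed").beta
        w = 1.0 / h.se_y**2
        q = float(np.sum(w * (h.by - beta * h.bx) ** 2))
        df = k - 1
    elif reference == "egger":
        if k < 3:
            raise InsufficientInstrumentsError("Q (Egger) needs >= 3 SNPs")
        est, pleio = estimators.mr_egger(h)
        sign = np.where(h.bx < 0, -1.0, 1.0)
        resid = h.by * sign - pleio.intercept - est.beta * h.bx * sign
        q = float(np.sum(resid**2 / h.se_y**2))
        df = k - 2
    else:
        raise ValueError(f"unknown Q reference {reference!r}")
    pval = float(sps.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, pval=pval, reference=reference)


def leave_one_out(
    h: HarmonizedSet, model: str = "multiplicative_random"
) -> LeaveOneOutResult:
    """IVW re-estimated with each SNP omitted, plus the all-SNP row."""
    from . import estimators

    if h.nsnp < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 SNPs")
    rows = []
    for j, snp in enumerate(h.snp_ids):
        mask = np.ones(h.nsnp, dtype=bool)
        mask[j] = False
        est = estimators.ivw(h.subset(mask), model=model)
        rows.append({"snp": snp, "beta": est.beta, "se": est.se, "pval": est.pval})
    full = estimators.ivw(h, model=model)
    rows.append({"snp": "All", "beta": full.beta, "se": full.se, "pval": full.pval})
    return LeaveOneOutResult(pd.DataFrame(rows))


def funnel_scatter_data(
    h: HarmonizedSet, panel: MRPanel
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plot-ready tables: funnel, scatter points, and per-method fit lines.

    The funnel table holds each SNP's Wald ratio against its precision
    (1 / first-order ratio SE).  The lines table gives one (slope, intercept)
    per estimated method; only MR-Egger has a non-zero intercept.
    """
    ratios = h.by / h.bx
    se_ratio = h.se_y / np.abs(h.bx)
    funnel = pd.DataFrame(
        {"snp": h.snp_ids, "ratio": ratios, "precision": 1.0 / se_ratio}
    )
    scatter = pd.DataFrame(
        {
            "snp": h.snp_ids,
            "bx": h.bx,
            "se_x": h.se_x,
            "by": h.by,
            "se_y": h.se_y,
        }
    )
    lines = []
    for method, est in panel.estimates.items():
        intercept = 0.0
        if method == "MR-Egger" and panel.pleiotropy is not None:
            intercept = panel.pleiotropy.intercept
        lines.append({"method": method, "slope": est.beta, "intercept": intercept})
    return funnel, scatter, pd.DataFrame(lines)
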