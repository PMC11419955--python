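"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mrmediate.datatypes import HarmonizedSet, SummaryStats


def make_harmonized(
    rng: np.random.Generator,
    k: int = 50,
    theta: float = 0.0,
    pleiotropy_sd: float = 0.0,
    intercept: float = 0.0,
    se_x: float = 0.01,
    se_y: float = 0.01,
    bx_sd: float = 0.15,
) -> HarmonizedSet:
    """Small direct generator of exposure-outcome effect pairs.

    Independent of the package's synthetic_data module so estimator tests
    have their own data route: true exposure effects ~ N(0, bx_sd), outcome
    effects theta * true + intercept + pleiotropy + noise.
    """
    bx_true = rng.normal(0.0, bx_sd, k)
    bx = bx_true + rng.normal(0.0, se_x, k)
    by = intercept + theta * bx_true + rng.normal(0.0, se_y, k)
    if pleiotropy_sd > 0:
        by = by + rng.normal(0.0, pleiotropy_sd, k)
    return HarmonizedSet(
        "exp", "out", [f"rs{i}" for i in range(k)],
        bx, np.full(k, se_x), by, np.full(k, se_y), np.full(k, 0.3),
    )


def harmonized_from_arrays(bx, by, se_x=None, se_y=None, eaf=None) -> HarmonizedSet:
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    k = len(bx)
    return HarmonizedSet(
        "exp", "out", [f"rs{i}" for i in range(k)],
        bx,
        np.full(k, 0.01) if se_x is None else np.asarray(se_x, dtype=float),
        by,
        np.full(k, 0.01) if se_y is None else np.asarray(se_y, dtype=float),
        np.full(k, 0.3) if eaf is None else np.asarray(eaf, dtype=float),
    )


def sumstats_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a summary-statistics frame from row dicts with defaults."""
    defaults = dict(chrom="1", pos=1000, effect_allele="A", other_allele="G",
                    eaf=0.3, beta=0.1, se=0.05, pval=0.01, n=1000)
    return pd.DataFrame([{**defaults, **row} for row in rows])


@pytest.fixture(scope="session")
def fixture_study():
    from mrmediate.simulate import study_shaped_fixture

    return study_shaped_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
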