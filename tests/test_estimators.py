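"""Estimator correctness against independent oracles and exact cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mrmediate import (
    DegenerateInputError,
    InsufficientInstrumentsError,
    ivw,
    mode_estimate,
    mr_egger,
    run_panel,
    wald_ratio,
    weighted_median,
)
from mrmediate.estimators import PanelSettings

from conftest import harmonized_from_arrays, make_harmonized

# ---------------------------------------------------------------- oracles


def ivw_oracle(h):
    """Origin-constrained WLS by direct summation."""
    w = 1.0 / h.se_y**2
    beta = np.sum(w * h.bx * h.by) / np.sum(w * h.bx**2)
    se = np.sqrt(1.0 / np.sum(w * h.bx**2))
    return beta, se


def egger_oracle(h):
    """Weighted normal equations with design [1, bx], bx oriented >= 0."""
    sign = np.where(h.bx < 0, -1.0, 1.0)
    bx, by = h.bx * sign, h.by * sign
    W = np.diag(1.0 / h.se_y**2)
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ W @ X
    coef = np.linalg.solve(xtwx, X.T @ W @ by)
    resid = by - X @ coef
    sigma2 = float(resid @ W @ resid) / (len(bx) - 2)
    cov = np.linalg.inv(xtwx) * max(sigma2, 1.0)
    return coef, np.sqrt(np.diag(cov))


def weighted_median_oracle(ratios, weights):
    """Exhaustive scan of the sorted-cumulative-weight definition."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    w = w / w.sum()
    s = np.cumsum(w) - 0.5 * w
    if s[0] >= 0.5:
        return r[0]
    for j in range(len(r) - 1):
        if s[j] < 0.5 <= s[j + 1]:
            return r[j] + (r[j + 1] - r[j]) * (0.5 - s[j]) / (s[j + 1] - s[j])
    return r[-1]


# ---------------------------------------------------------------- wald


class TestWaldRatio:
    def test_direct_substitution(self):
        est = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome_effect(self):
        est = wald_ratio(0.1, 0.01, 0.0, 0.01)
        assert est.beta == 0.0
        assert est.or_ == 1.0

    def test_matches_arithmetic_on_random_inputs(self, rng):
        for _ in range(50):
            bx, by = rng.normal(size=2)
            if bx == 0:
                continue
            se_y = rng.uniform(0.01, 1)
            est = wald_ratio(bx, 0.1, by, se_y)
            assert est.beta == pytest.approx(by / bx)
            assert est.se == pytest.approx(se_y / abs(bx))

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(DegenerateInputError):
            wald_ratio(0.0, 0.01, 0.1, 0.01)


# ---------------------------------------------------------------- ivw


class TestIVW:
    def test_identical_ratios_recovered_exactly(self):
        h = harmonized_from_arrays([0.1, 0.2], [0.05, 0.10])
        assert ivw(h).beta == pytest.approx(0.5, rel=1e-12)

    def test_matches_wls_oracle(self, rng):
        for _ in range(30):
            k = int(rng.integers(5, 21))
            h = make_harmonized(rng, k=k, theta=rng.normal(), pleiotropy_sd=0.02)
            beta, se_fixed = ivw_oracle(h)
            assert ivw(h, model="fixed").beta == pytest.approx(beta, rel=1e-10)
            assert ivw(h, model="fixed").se == pytest.approx(se_fixed, rel=1e-10)
            # random-effects se never below the fixed-effect se
            assert ivw(h).se >= se_fixed * (1 - 1e-12)

    def test_simulation_recovers_true_effect(self, rng):
        h = make_harmonized(np.random.default_rng(42), k=50, theta=0.30,
                            se_y=0.01)
        est = ivw(h)
        _, se_oracle = ivw_oracle(h)
        assert abs(est.beta - 0.30) < 3 * se_oracle

    def test_single_snp_equals_wald_ratio(self):
        h = harmonized_from_arrays([0.2], [0.1], se_y=[0.03])
        est = ivw(h)
        ref = wald_ratio(0.2, 0.01, 0.1, 0.03)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_invariant_to_joint_negation_of_any_snp(self, rng):
        h = make_harmonized(rng, k=10, theta=0.4)
        base = ivw(h).beta
        h.bx[3] *= -1
        h.by[3] *= -1
        assert ivw(h).beta == pytest.approx(base, rel=1e-12)

    def test_all_zero_exposure_effects_raise(self):
        h = harmonized_from_arrays([0.0, 0.0], [0.1, 0.2])
        with pytest.raises(DegenerateInputError):
            ivw(h)


# ---------------------------------------------------------------- egger


class TestMREgger:
    def test_noiseless_linear_data_recovered_exactly(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        by = 0.02 + 0.5 * bx
        h = harmonized_from_arrays(bx, by)
        est, pleio = mr_egger(h)
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert pleio.intercept == pytest.approx(0.02, abs=1e-12)

    def test_proportional_data_has_null_intercept(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2, 0.3])
        h = harmonized_from_arrays(bx, 0.5 * bx)
        est, pleio = mr_egger(h)
        assert pleio.intercept == pytest.approx(0.0, abs=1e-12)
        assert pleio.pval > 0.99

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(30):
            k = int(rng.integers(5, 21))
            h = make_harmonized(rng, k=k, theta=0.3, intercept=0.01,
                                pleiotropy_sd=0.02)
            est, pleio = mr_egger(h)
            coef, se = egger_oracle(h)
            assert pleio.intercept == pytest.approx(coef[0], rel=1e-8)
            assert est.beta == pytest.approx(coef[1], rel=1e-8)
            assert pleio.se == pytest.approx(se[0], rel=1e-8)
            assert est.se == pytest.approx(se[1], rel=1e-8)

    def test_pvalues_use_t_distribution(self, rng):
        h = make_harmonized(rng, k=8, theta=0.3, pleiotropy_sd=0.05)
        est, _ = mr_egger(h)
        assert est.pval == pytest.approx(
            2 * sps.t.sf(abs(est.beta) / est.se, df=6), rel=1e-10
        )

    def test_too_few_instruments_raise(self):
        h = harmonized_from_arrays([0.1, 0.2], [0.05, 0.1])
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(h)

    def test_no_spread_in_exposure_effects_raises(self):
        h = harmonized_from_arrays([0.1, 0.1, -0.1], [0.05, 0.04, -0.06])
        with pytest.raises(DegenerateInputError):
            mr_egger(h)


# ---------------------------------------------------------------- median


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_middle_element(self):
        h = harmonized_from_arrays([1.0, 1.0, 1.0], [0.2, 0.5, 0.9])
        est = weighted_median(h, n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_identical_ratios_degenerate(self):
        h = harmonized_from_arrays([0.1, 0.2, 0.4], [0.03, 0.06, 0.12])
        est = weighted_median(h, n_boot=200, seed=0)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 0.35  # bootstrap noise only

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(3, 9))
            h = make_harmonized(rng, k=k, theta=0.5, pleiotropy_sd=0.05)
            est = weighted_median(h, n_boot=10, seed=0)
            expected = weighted_median_oracle(h.by / h.bx, (h.bx / h.se_y) ** 2)
            assert est.beta == pytest.approx(expected, rel=1e-10)

    @given(st.lists(st.floats(-2, 2), min_size=3, max_size=9, unique=True))
    @settings(max_examples=50, derandomize=True)
    def test_equal_weights_odd_count_equals_sample_median(self, ratios):
        if len(ratios) % 2 == 0:
            ratios = ratios[:-1]
        h = harmonized_from_arrays(np.ones(len(ratios)), np.array(ratios))
        est = weighted_median(h, n_boot=5, seed=0)
        assert est.beta == pytest.approx(float(np.median(ratios)), rel=1e-9)


# ---------------------------------------------------------------- mode


class TestModeEstimators:
    def test_dominant_cluster_wins(self):
        h = harmonized_from_arrays(np.ones(4), [0.5, 0.5, 0.5, 2.0])
        est = mode_estimate(h, weighted=False, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_all_ratios_equal_returns_common_ratio(self):
        h = harmonized_from_arrays([0.1, 0.2, 0.5], [0.07, 0.14, 0.35])
        est = mode_estimate(h, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.7)
        assert est.se == 0.0
        assert "degenerate_ratios" in est.flags

    def test_argmax_matches_dense_grid_oracle(self, rng):
        for _ in range(10):
            h = make_harmonized(rng, k=7, theta=0.4, pleiotropy_sd=0.05)
            for weighted in (False, True):
                est = mode_estimate(h, weighted=weighted, n_boot=5, seed=0)
                ratios = h.by / h.bx
                w = (np.abs(h.bx) / h.se_y) ** 2 if weighted else np.ones(7)
                w = w / w.sum()
                sd = ratios.std(ddof=1)
                iqr = np.subtract(*np.percentile(ratios, [75, 25]))
                bw = 0.9 * min(sd, iqr / 1.349) * 7 ** (-0.2)
                grid = np.linspace(ratios.min(), ratios.max(), 50_001)
                dens = (np.exp(-0.5 * ((grid[:, None] - ratios) / bw) ** 2) @ w)
                oracle = grid[np.argmax(dens)]
                span = ratios.max() - ratios.min()
                assert abs(est.beta - oracle) <= span / 300


# ---------------------------------------------------------------- panel


class TestRunPanel:
    def test_single_snp_dispatches_wald_only(self):
        h = harmonized_from_arrays([0.2], [0.1])
        panel = run_panel(h, PanelSettings(n_boot=10, seed=0))
        assert set(panel.estimates) == {"Wald"}
        assert "IVW" in panel.skipped

    def test_full_panel_at_study_scale(self, rng):
        h = make_harmonized(rng, k=28, theta=0.3, pleiotropy_sd=0.02)
        panel = run_panel(h, PanelSettings(n_boot=50, seed=0))
        assert set(panel.estimates) == {
            "IVW", "MR-Egger", "weighted_median", "simple_mode", "weighted_mode"
        }
        assert panel.pleiotropy is not None
        assert set(panel.heterogeneity) == {"ivw", "egger"}

    def test_or_ci_printed_format(self):
        # the emulated study prints OR 1.962 with 95% CI (1.298, 2.964);
        # endpoints are reproduced to within one unit in the last digit
        beta = np.log(1.962)
        se = (np.log(2.964) - np.log(1.298)) / (2 * 1.96)
        h = harmonized_from_arrays([1.0], [beta], se_y=[se])
        est = run_panel(h).estimates["Wald"]
        assert est.or_ == pytest.approx(1.962, abs=5e-4)
        assert est.ci_low == pytest.approx(1.298, abs=2e-3)
        assert est.ci_high == pytest.approx(2.964, abs=2e-3)
        assert est.format_or() == "1.962 (1.298, 2.965)"
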