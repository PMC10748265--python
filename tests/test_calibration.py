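"""Calibration fitting, splitting, backcalculation, and linearity criteria."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from chromval.calibration import (
    accordance,
    assess_linearity,
    backcalculate,
    fit_ols,
    select_curve,
    slope_rsd,
    split_curves,
)
from chromval.errors import DegenerateDesignError
from chromval.synthetic import STANDARD_LEVELS, ResponseModel, simulate_area_table
from conftest import make_curve


def normal_equations(x, y):
    """Independent OLS oracle: explicit normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    m = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    b = y.mean() - m * x.mean()
    return m, b, sxx, n


class TestFitOLS:
    def test_perfect_line(self):
        curve = fit_ols([0, 1, 2], [0, 1, 2])
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r2 == pytest.approx(1.0)

    def test_hand_computed_normal_equations(self):
        curve = fit_ols([1, 2, 3], [2, 3, 5])
        assert curve.slope == pytest.approx(1.5)
        assert curve.intercept == pytest.approx(1 / 3)

    def test_simulator_round_trip_exact(self, noiseless_response):
        table = simulate_area_table(list(STANDARD_LEVELS), noiseless_response,
                                    replicates=3, days=1, seed=0)
        curve = fit_ols(table["concentration_ug_per_ml"], table["area"])
        assert curve.slope == pytest.approx(15485.0, rel=1e-12)
        assert curve.intercept == pytest.approx(11659.0, rel=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_ols([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 2**31 - 1))
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        x = rng.uniform(0, 100, n)
        while np.unique(x).size < 3:
            x = rng.uniform(0, 100, n)
        y = rng.uniform(0, 1e6, n)
        curve = fit_ols(x, y)
        m, b, _, _ = normal_equations(x, y)
        assert curve.slope == pytest.approx(m, rel=1e-10)
        assert curve.intercept == pytest.approx(b, rel=1e-10, abs=1e-8)


class TestSplitCurves:
    def test_reference_design_split_at_5(self, noiseless_response):
        table = simulate_area_table(list(STANDARD_LEVELS), noiseless_response,
                                    seed=0)
        low, high = split_curves(table["concentration_ug_per_ml"],
                                 table["area"], 5.0)
        assert (low.range_low, low.range_high) == (0.14, 5.0)
        assert (high.range_low, high.range_high) == (5.0, 245.0)
        assert low.n_levels == high.n_levels == 5  # split level in both

    def test_collinear_subcurves_reproduce_global_line(self, noiseless_response):
        table = simulate_area_table(list(STANDARD_LEVELS), noiseless_response,
                                    seed=0)
        low, high = split_curves(table["concentration_ug_per_ml"],
                                 table["area"], 5.0)
        for c in (low, high):
            assert c.slope == pytest.approx(15485.0, rel=1e-10)
            assert c.intercept == pytest.approx(11659.0, rel=1e-8)

    def test_absent_split_level_rejected(self):
        x = np.repeat(STANDARD_LEVELS, 2)
        with pytest.raises(DegenerateDesignError, match="not among"):
            split_curves(x, 2 * x, split_concentration=7.7)

    def test_too_few_levels_names_the_side(self):
        x = np.array([1, 2, 3, 4, 5, 6.0])
        with pytest.raises(DegenerateDesignError, match="high"):
            split_curves(x, 2 * x, split_concentration=5.0)

    def test_split_reduces_residual_dispersion_within_each_range(self):
        # the motivation for splitting: under heteroscedastic noise the
        # global line is pulled by the high levels, so a dedicated sub-range
        # fit scatters less over its own range than the global line does
        # over those same points
        response = ResponseModel(cv_proportional=0.05)
        table = simulate_area_table(list(STANDARD_LEVELS), response,
                                    replicates=3, days=5, seed=42)
        x = table["concentration_ug_per_ml"].to_numpy()
        y = table["area"].to_numpy()
        full = fit_ols(x, y)
        low, high = split_curves(x, y, 5.0)

        for curve in (low, high):
            mask = (x >= curve.range_low) & (x <= curve.range_high)
            n = mask.sum()
            global_sd = np.sqrt(
                np.sum((y[mask] - full.predict(x[mask])) ** 2) / (n - 2)
            )
            assert curve.residual_sd <= global_sd

    def test_select_curve_by_range(self):
        low = make_curve(15262.0, -271.48, range_low=0.14, range_high=5.0)
        high = make_curve(15317.0, 42292.0, range_low=5.0, range_high=245.0)
        assert select_curve(low, high, 0.35) is low
        assert select_curve(low, high, 5.0) is low
        assert select_curve(low, high, 125.0) is high


class TestBackcalculation:
    def test_area_equal_to_intercept_gives_zero(self):
        curve = make_curve(15485.0, 11659.0)
        assert backcalculate(curve, 11659.0) == pytest.approx(0.0)

    def test_low_standard_under_full_curve_goes_negative(self):
        # the lowest standard reads below the full-range intercept, so the
        # nonadjusted curve backcalculates it negative; pushing the same
        # area through the low-range adjusted curve recovers ~0.15 ug/mL
        nonadj = make_curve(15485.0, 11659.0)
        adj1 = make_curve(15262.0, -271.48)
        area = nonadj.predict(-0.62)  # 2058.3
        assert area == pytest.approx(2058.3)
        assert backcalculate(adj1, area) == pytest.approx(0.15, abs=0.005)

    def test_forward_then_invert_identity_at_table_level(self):
        adj1 = make_curve(15262.0, -271.48)
        assert backcalculate(adj1, 42462.1) == pytest.approx(2.80, abs=0.005)

    @given(st.floats(-1e3, 1e3))
    def test_forward_inverse_identity(self, c):
        curve = make_curve(15485.0, 11659.0)
        assert backcalculate(curve, curve.predict(c)) == pytest.approx(
            c, rel=1e-12, abs=1e-9
        )

    def test_zero_slope_rejected(self):
        bad = make_curve(0.0, 0.0)
        with pytest.raises(DegenerateDesignError):
            backcalculate(bad, 1.0)


class TestAccordance:
    @pytest.mark.parametrize(
        "nominal, obtained, expected",
        [(0.14, 0.15, 107.0), (5.0, 2.2, 44.0), (3.3, 3.3, 100.0)],
    )
    def test_reference_values(self, nominal, obtained, expected):
        assert accordance(nominal, obtained) == pytest.approx(expected, abs=0.2)

    def test_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError):
            accordance(0.0, 1.0)

    def test_noiseless_standards_read_100_under_own_curve(self, noiseless_response):
        table = simulate_area_table(list(STANDARD_LEVELS), noiseless_response,
                                    seed=0)
        curve = fit_ols(table["concentration_ug_per_ml"], table["area"])
        for level in STANDARD_LEVELS:
            obtained = backcalculate(curve, noiseless_response.expected(level))
            assert accordance(level, obtained) == pytest.approx(100.0, abs=1e-8)


class TestLinearityCriteria:
    @pytest.mark.parametrize(
        "slope, slope_sd, expected",
        [(15485.0, 289.47, 1.87), (15262.0, 211.13, 1.38),
         (15317.0, 601.69, 3.93), (15485.0, 0.0, 0.0)],
    )
    def test_slope_rsd(self, slope, slope_sd, expected):
        curve = make_curve(slope, 0.0, slope_sd=slope_sd)
        assert slope_rsd(curve) == pytest.approx(expected, abs=0.005)

    def test_zero_in_ci_flags(self):
        inside = make_curve(1.0, -271.48, intercept_sd=500.0, n_points=15)
        outside = make_curve(1.0, 1.5, intercept_sd=0.1, n_points=15)
        assert assess_linearity(inside).zero_in_ci
        assert not assess_linearity(outside).zero_in_ci

    def test_ci_matches_brute_force_t_oracle(self, rng):
        x = np.array([0.14, 0.35, 0.57, 2.8, 5.0] * 3)
        y = 15262.0 * x - 271.48 + rng.normal(0, 300, x.size)
        curve = fit_ols(x, y)
        assessment = assess_linearity(curve, confidence=0.95)
        # independent oracle: explicit OLS formulas + t quantile
        m, b, sxx, n = normal_equations(x, y)
        s = np.sqrt(np.sum((y - m * x - b) ** 2) / (n - 2))
        se_b = s * np.sqrt(1 / n + x.mean() ** 2 / sxx)
        tq = stats.t.ppf(0.975, n - 2)
        assert assessment.intercept_ci[0] == pytest.approx(b - tq * se_b, rel=1e-9)
        assert assessment.intercept_ci[1] == pytest.approx(b + tq * se_b, rel=1e-9)

    def test_pass_flags_follow_thresholds(self):
        good = make_curve(15262.0, -271.48, slope_sd=211.13,
                          intercept_sd=500.0, r=0.9997, n_points=15)
        a = assess_linearity(good)
        assert a.slope_rsd_pass and a.r_pass and a.passed
        weak = make_curve(100.0, 0.0, slope_sd=10.0, intercept_sd=1.0,
                          r=0.95, n_points=15)
        b = assess_linearity(weak)
        assert not b.slope_rsd_pass and not b.r_pass and not b.passed
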