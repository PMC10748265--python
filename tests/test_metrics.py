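"""Sensitivity, precision, accuracy, stability, robustness, selectivity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chromval.metrics import (
    LOQ_LOD_RATIO,
    PeakSummary,
    accuracy,
    lod_loq,
    precision,
    robustness_compare,
    selectivity_check,
    stability,
)
from chromval.peaks import assign_and_resolve, detect_peaks
from chromval.synthetic import (
    PeakModel,
    ResponseModel,
    simulate_area_table,
    simulate_trace,
)
from conftest import make_curve


class TestSensitivity:
    def test_hand_arithmetic(self, rng):
        # delta = 100, slope = 3300: LOD = 3.3*100/3300 = 0.1, LOQ = 0.3030
        blanks = 100.0 * rng.standard_normal(2000)
        res = lod_loq(blanks, 3300.0)
        assert res.lod == pytest.approx(0.1, rel=0.05)
        assert res.loq == pytest.approx(0.30303, rel=0.05)

    def test_identical_blanks_give_zero_limits(self):
        res = lod_loq([500.0, 500.0, 500.0], 15262.0)
        assert res.lod == 0.0 and res.loq == 0.0

    def test_printed_pair_consistency(self):
        # a blank SD chosen so LOD = 0.046 must put LOQ at 0.1394,
        # i.e. the reported (0.046, 0.14) pair is self-consistent
        delta = 0.046 * 15262.0 / 3.3
        res = lod_loq([0.0, delta * np.sqrt(2)], 15262.0)  # sample SD = delta
        assert res.lod == pytest.approx(0.046, rel=1e-9)
        assert res.loq == pytest.approx(0.1394, abs=0.0005)
        assert round(res.loq, 2) == 0.14

    @given(st.floats(1.0, 1e6), st.floats(1.0, 1e6))
    def test_loq_lod_ratio_exact(self, spread, slope):
        # exact by construction, up to one rounding of the final division
        res = lod_loq([0.0, spread], slope)
        assert res.loq / res.lod == pytest.approx(LOQ_LOD_RATIO, rel=1e-15)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            lod_loq([1.0], 10.0)
        with pytest.raises(ValueError):
            lod_loq([1.0, 2.0], 0.0)


def table_from_values(values, level=10.0, days=None):
    import pandas as pd

    values = np.asarray(values, float)
    days = np.ones(values.size, int) if days is None else np.asarray(days)
    return pd.DataFrame({
        "analyte": "quercetin",
        "concentration_ug_per_ml": level,
        "replicate": np.arange(1, values.size + 1),
        "day": days,
        "condition": "fresh",
        "area": values,
    })


class TestPrecision:
    def test_hand_rsd(self):
        # SD(9,10,11) = 1, mean = 10 -> 10%
        res = precision(table_from_values([9.0, 10.0, 11.0]), 10.0, "intraday")
        assert res.intraday_rsd == pytest.approx(10.0)
        assert res.interday_rsd is None

    def test_identical_observations_zero_rsd(self):
        res = precision(table_from_values([5.0] * 6, days=[1, 1, 1, 2, 2, 2]),
                        10.0, "both")
        assert res.intraday_rsd == 0.0 and res.interday_rsd == 0.0
        assert res.passed

    def test_interday_pools_across_days(self):
        # two tight days at different means: intraday small, interday large
        vals = [100.0, 101.0, 99.0, 120.0, 121.0, 119.0]
        res = precision(table_from_values(vals, days=[1, 1, 1, 2, 2, 2]),
                        10.0, "both")
        assert res.intraday_rsd < 2.0
        assert res.interday_rsd > 5.0

    def test_backcalculated_vs_area_choice(self):
        # with a nonzero intercept the two conventions disagree
        vals = [1000.0, 1100.0, 900.0]
        curve = make_curve(10.0, 500.0)
        on_area = precision(table_from_values(vals), 10.0, "intraday")
        on_conc = precision(table_from_values(vals), 10.0, "intraday", curve)
        assert on_conc.intraday_rsd > on_area.intraday_rsd

    @given(st.floats(1e-3, 1e3))
    def test_rsd_scale_invariance(self, k):
        vals = np.array([9.0, 10.0, 11.0, 10.5, 9.5])
        a = precision(table_from_values(vals), 10.0, "intraday")
        b = precision(table_from_values(k * vals), 10.0, "intraday")
        assert b.intraday_rsd == pytest.approx(a.intraday_rsd, rel=1e-9)

    def test_monte_carlo_envelope_at_reference_level(self):
        # 15 measurements at 125 ug/mL with 5% proportional noise: the
        # intraday RSD stays within a 2-9% envelope across 100 seeds,
        # bracketing repeatability figures of a few percent
        response = ResponseModel(cv_proportional=0.05)
        for seed in range(100):
            table = simulate_area_table([125.0], response, replicates=15,
                                        days=1, seed=seed)
            res = precision(table, 125.0, "intraday")
            assert 2.0 <= res.intraday_rsd <= 9.0

    def test_absent_level_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            precision(table_from_values([1.0, 2.0, 3.0]), 99.0, "intraday")

    def test_interday_needs_two_days(self):
        with pytest.raises(ValueError, match="2 days"):
            precision(table_from_values([1.0, 2.0, 3.0]), 10.0, "interday")


class TestAccuracy:
    @pytest.mark.parametrize(
        "nominal, obtained, expected",
        [(0.35, 0.31, 88.6), (196.0, 217.0, 110.7), (7.0, 7.0, 100.0)],
    )
    def test_reference_percentages(self, nominal, obtained, expected):
        curve = make_curve(1.0, 0.0)  # identity line: areas are concentrations
        table = table_from_values([obtained] * 3, level=nominal)
        res = accuracy(table, nominal, curve)
        assert res.accuracy == pytest.approx(expected, abs=0.05)

    def test_band_flag(self):
        curve = make_curve(1.0, 0.0)
        low = accuracy(table_from_values([7.0] * 3, level=10.0), 10.0, curve)
        assert not low.passed  # 70%
        ok = accuracy(table_from_values([9.0] * 3, level=10.0), 10.0, curve)
        assert ok.passed  # 90%

    @given(st.floats(0.1, 1e3))
    def test_homogeneous_degree_zero(self, k):
        curve = make_curve(1.0, 0.0)
        a = accuracy(table_from_values([8.0] * 3, level=10.0), 10.0, curve)
        b = accuracy(table_from_values([8.0 * k] * 3, level=10.0 * k),
                     10.0 * k, curve)
        assert b.accuracy == pytest.approx(a.accuracy, rel=1e-9)

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError):
            accuracy(table_from_values([1.0] * 3, level=0.0), 0.0,
                     make_curve(1.0, 0.0))


class TestStability:
    @pytest.mark.parametrize(
        "day0, dayx, day, expected",
        [(7129.0, 7929.0, 5, 111.22), (7799.0, 5336.0, 7, 68.42)],
    )
    def test_reference_grid_values(self, day0, dayx, day, expected):
        res = stability([day0], [dayx], day)
        assert round(res.stability, 2) == expected

    def test_identical_means_are_100(self):
        res = stability([10.0, 20.0], [15.0, 15.0], 5)
        assert res.stability == pytest.approx(100.0)

    def test_day_zero_is_exactly_100(self):
        vals = [7129.0, 7100.0, 7150.0]
        assert stability(vals, vals, 0).stability == 100.0

    @given(st.floats(0.1, 1e3))
    def test_homogeneous_degree_zero(self, k):
        a = stability([10.0, 12.0], [9.0, 11.0], 5)
        b = stability([10.0 * k, 12.0 * k], [9.0 * k, 11.0 * k], 5)
        assert b.stability == pytest.approx(a.stability, rel=1e-9)

    def test_zero_day0_rejected(self):
        with pytest.raises(ValueError):
            stability([0.0, 0.0], [1.0], 5)


class TestRobustness:
    def test_ph_scenario(self):
        res = robustness_compare(PeakSummary(7_304_837.0, 3.8),
                                 PeakSummary(6_741_931.0, 3.8), "pH")
        assert round(res.area_percent, 2) == 92.29
        assert res.rt_difference == pytest.approx(0.0)

    def test_flow_scenario(self):
        res = robustness_compare(PeakSummary(6_111_868.0, 3.7),
                                 PeakSummary(4_299_546.0, 2.4), "flow_rate")
        assert round(res.area_percent, 2) == 70.35
        assert res.rt_difference == pytest.approx(-1.3)

    def test_identity(self):
        p = PeakSummary(1000.0, 3.6)
        res = robustness_compare(p, p)
        assert res.area_percent == 100.0 and res.rt_difference == 0.0

    def test_zero_optimized_area_rejected(self):
        with pytest.raises(ValueError):
            robustness_compare(PeakSummary(0.0, 3.6), PeakSummary(1.0, 3.6))


class TestSelectivity:
    EXPECTED = {"rutin": 2.5, "quercetin": 3.6, "kaempferol": 5.4}

    def _assignment(self, names=None):
        rts = {k: v for k, v in self.EXPECTED.items()
               if names is None or k in names}
        peaks = [PeakModel(n, rt, area=1e6) for n, rt in
                 sorted(rts.items(), key=lambda kv: kv[1])]
        trace = simulate_trace(peaks, noise_sd=20.0, seed=13)
        return assign_and_resolve(detect_peaks(trace, 1000.0), self.EXPECTED)

    def test_full_separation_passes(self):
        res = selectivity_check(self._assignment(), set(self.EXPECTED))
        assert res.passed
        assert set(res.matched) == set(self.EXPECTED)
        assert all(rs >= 1.5 for _, rs in res.resolutions)

    def test_missing_analyte_named(self):
        res = selectivity_check(self._assignment({"rutin", "kaempferol"}),
                                set(self.EXPECTED))
        assert not res.passed
        assert any("quercetin" in m for m in res.messages)

    def test_duplicate_assignment_narrative(self):
        assignment = self._assignment()
        for p in assignment.peaks:
            p.assigned_analyte = "quercetin"  # corrupt: all claim quercetin
        res = selectivity_check(assignment, set(self.EXPECTED))
        assert not res.passed
        assert any("ambiguous" in m for m in res.messages)

    def test_low_resolution_fails(self):
        res = selectivity_check(self._assignment(), set(self.EXPECTED),
                                min_resolution=50.0)
        assert not res.passed
        assert any("resolution" in m for m in res.messages)
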