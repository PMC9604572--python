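import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clvsim import ControllerConfig, TargetBand, report_case, varvel_metrics
from clvsim.metrics import (
    UndefinedMetricError,
    band_time_fractions,
    dose_summary,
    pct_map_below,
    performance_error,
    pump_activity,
    rate_change_count,
)

from conftest import build_series

BAND = TargetBand(target=130.0, fraction=0.10)


class TestBandTimeFractions:
    def test_all_at_target(self):
        s = build_series([130.0] * 5)
        assert band_time_fractions(s, BAND) == (0.0, 100.0, 0.0)

    def test_ten_sample_split(self):
        s = build_series([110.0] + [130.0] * 8 + [150.0])
        assert band_time_fractions(s, BAND) == (10.0, 80.0, 10.0)

    def test_boundary_counts_in_band(self):
        s = build_series([117.0, 143.0])
        assert band_time_fractions(s, BAND) == (0.0, 100.0, 0.0)

    def test_invalid_samples_excluded(self):
        s = build_series([110.0, 130.0], valid=[False, True])
        assert band_time_fractions(s, BAND) == (0.0, 100.0, 0.0)

    def test_no_valid_samples_undefined(self):
        s = build_series([130.0, 130.0], valid=[False, False])
        with pytest.raises(UndefinedMetricError):
            band_time_fractions(s, BAND)

    @given(
        sap=st.lists(st.floats(60.0, 220.0), min_size=1, max_size=80),
        shift=st.floats(0.0, 30.0),
    )
    def test_conservation_and_shift_monotonicity(self, sap, shift):
        s = build_series(sap)
        under, inb, over = band_time_fractions(s, BAND)
        assert under + inb + over == pytest.approx(100.0, abs=1e-9)
        u2, _, o2 = band_time_fractions(build_series(np.array(sap) + shift), BAND)
        assert u2 <= under and o2 >= over


class TestSimpleFractions:
    def test_map_none_below(self):
        s = build_series([130.0] * 4, map_mmhg=[70.0] * 4)
        assert pct_map_below(s, 65.0) == 0.0

    def test_map_one_of_four(self):
        s = build_series([130.0] * 4, map_mmhg=[70.0, 60.0, 70.0, 70.0])
        assert pct_map_below(s, 65.0) == 25.0

    def test_map_threshold_is_strict(self):
        s = build_series([130.0], map_mmhg=[65.0])
        assert pct_map_below(s, 65.0) == 0.0

    @pytest.mark.parametrize(
        "rates,expected",
        [([0.0, 0.0, 0.0, 0.0], 0.0), ([5.0, 5.0, 5.0, 5.0], 100.0), ([2.0, 2.0, 2.0, 0.0], 75.0)],
    )
    def test_pump_activity(self, rates, expected):
        assert pump_activity(build_series([130.0] * 4, rate=rates)) == expected


class TestRateChanges:
    def test_constant_rate_no_changes(self):
        s = build_series([130.0] * 4, rate=[5.0] * 4)
        assert rate_change_count(s) == 0.0

    def test_alternating_rate_three_per_minute(self):
        # 4 samples spanning 60 s with 3 changes → 3/min
        s = build_series([130.0] * 4, rate=[2.0, 4.0, 2.0, 4.0])
        assert rate_change_count(s) == pytest.approx(3.0)

    def test_subepsilon_changes_ignored(self):
        s = build_series([130.0] * 4, rate=[2.0, 2.01, 2.0, 2.01])
        assert rate_change_count(s, rate_epsilon=0.05) == 0.0

    def test_needs_two_samples(self):
        with pytest.raises(UndefinedMetricError):
            rate_change_count(build_series([130.0], rate=[2.0]))


class TestDoseSummary:
    def test_constant_rate_hour(self):
        # 180 samples × 20 s = 60 min at 6 µg/min → 360 µg
        s = build_series([130.0] * 180, rate=[6.0] * 180)
        assert dose_summary(s) == (pytest.approx(360.0), pytest.approx(6.0))

    def test_zero_rate(self):
        assert dose_summary(build_series([130.0] * 10)) == (0.0, 0.0)

    def test_half_on_half_off(self):
        s = build_series([130.0] * 60, rate=[0.0] * 30 + [10.0] * 30)
        _, mean_rate = dose_summary(s)
        assert mean_rate == pytest.approx(5.0)


class TestPerformanceError:
    @pytest.mark.parametrize("sap,pe", [(130.0, 0.0), (143.0, 10.0), (117.0, -10.0)])
    def test_values(self, sap, pe):
        out, _ = performance_error(build_series([sap]), BAND)
        assert out[0] == pytest.approx(pe)

    def test_timestamps_are_valid_samples_only(self):
        s = build_series([130.0, 120.0, 130.0], valid=[True, False, True])
        pe, t = performance_error(s, BAND)
        assert len(pe) == 2 and list(t) == [0.0, 40.0]


def brute_force_varvel(pe, t_min):
    """Independent oracle: sort-based medians + normal-equation OLS slope."""
    def med(v):
        v = sorted(v)
        n = len(v)
        return v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])

    mdpe = med(list(pe))
    mdape = med([abs(x) for x in pe])
    wobble = med([abs(x - mdpe) for x in pe])
    x = [tt / 60.0 for tt in t_min]  # hours
    y = [abs(v) for v in pe]
    n = len(x)
    sx, sy, sxx, sxy = sum(x), sum(y), sum(a * a for a in x), sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    return mdpe, mdape, wobble, slope


class TestVarvelMetrics:
    def test_hand_medians(self):
        pe = np.array([0.0, 10.0, -10.0, 5.0, -5.0])
        t = np.arange(5) * 20.0
        mdpe, mdape, wobble, _ = varvel_metrics(pe, t)
        assert (mdpe, mdape, wobble) == (0.0, 5.0, 5.0)

    def test_divergence_closed_form(self):
        # |PE| rising 2→8 over 30 min: slope 0.2 %/min = 12 %/h
        pe = np.array([2.0, 4.0, 6.0, 8.0])
        t = np.array([0.0, 10.0, 20.0, 30.0]) * 60.0
        assert varvel_metrics(pe, t)[3] == pytest.approx(12.0)
        assert varvel_metrics(pe, t, divergence_per="min")[3] == pytest.approx(0.2)

    def test_constant_pe(self):
        pe = np.full(10, 3.0)
        t = np.arange(10) * 20.0
        mdpe, mdape, wobble, div = varvel_metrics(pe, t)
        assert (mdpe, mdape, wobble) == (3.0, 3.0, 0.0)
        assert div == pytest.approx(0.0, abs=1e-9)

    @given(
        pe=st.lists(st.floats(-50.0, 50.0), min_size=2, max_size=60),
    )
    def test_matches_brute_force_oracle(self, pe):
        t = np.arange(len(pe)) * 20.0
        ours = varvel_metrics(np.array(pe), t)
        oracle = brute_force_varvel(pe, t / 60.0)
        assert np.allclose(ours, oracle, atol=1e-9)

    @given(pe=st.lists(st.floats(-100.0, 100.0), min_size=2, max_size=60))
    def test_mdape_dominates_bias(self, pe):
        t = np.arange(len(pe)) * 20.0
        mdpe, mdape, wobble, _ = varvel_metrics(np.array(pe), t)
        assert mdape >= abs(mdpe) - 1e-12
        assert wobble >= 0.0


class TestReportCase:
    def test_constant_in_band_series(self):
        s = build_series([130.0] * 20, rate=[4.0] * 20)
        rep = report_case(s, cfg=ControllerConfig())
        assert rep.pct_in == 100.0 and rep.pct_under == 0.0
        assert rep.mdape == 0.0 and rep.wobble == 0.0
        assert rep.divergence == pytest.approx(0.0, abs=1e-9)
        assert rep.pct_pump_active == 100.0

    def test_composition_matches_parts(self):
        s = build_series([110.0] + [130.0] * 8 + [150.0], rate=list(range(10)))
        rep = report_case(s, cfg=ControllerConfig())
        assert (rep.pct_under, rep.pct_in, rep.pct_over) == (10.0, 80.0, 10.0)
        assert rep.total_dose == pytest.approx(sum(range(10)) * 20.0 / 60.0)

    def test_rescoring_is_deterministic(self):
        s = build_series(np.linspace(100.0, 160.0, 40), rate=np.linspace(0, 8, 40))
        assert report_case(s, cfg=ControllerConfig()) == report_case(s, cfg=ControllerConfig())
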