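import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcturnover import (
    ExponentialDecayFit,
    InvalidInputError,
    LinearTurnoverRegressor,
    as_timecourse,
    estimate_egress_rate_brdu,
    fit_exponential_decay,
    fit_linear_turnover,
    gen_exponential_photoconversion,
    gen_linear_photoconversion,
    replaced_fraction_at,
    summarize_maturation_bins,
)


def linear_series(intercept, slope, times):
    return as_timecourse(times, [intercept + slope * t for t in times])


class TestLinearTurnover:
    @pytest.mark.parametrize(
        "intercept, slope, times, t50, complete",
        [
            # default photoconversion series: half replaced in ~2.9 days
            (98.7, -16.8, (0, 1, 2, 3), (98.7 - 50) / 16.8, 2 * (98.7 - 50) / 16.8),
            (90.0, -10.0, (0, 1, 2), 4.0, 8.0),
        ],
    )
    def test_recovers_line_and_t50(self, intercept, slope, times, t50, complete):
        fit = fit_linear_turnover(linear_series(intercept, slope, times))
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        assert fit.t50 == pytest.approx(t50, abs=1e-9)
        assert fit.complete_turnover_time == pytest.approx(complete, abs=1e-9)
        assert fit.daily_turnover_rate == pytest.approx(abs(slope))
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.t50_defined

    def test_flat_series_has_undefined_t50(self):
        fit = fit_linear_turnover(as_timecourse([0, 1, 2, 3], [100] * 4))
        assert fit.slope == pytest.approx(0.0)
        assert not fit.t50_defined
        assert math.isnan(fit.t50)

    def test_below_50_intercept_flagged_not_raised(self):
        fit = fit_linear_turnover(linear_series(40.0, -5.0, (0, 1, 2)))
        assert not fit.t50_defined

    def test_requires_two_distinct_times(self):
        with pytest.raises(InvalidInputError):
            fit_linear_turnover(as_timecourse([1, 1], [90, 92]))

    def test_hours_are_converted_to_days(self):
        tc = as_timecourse([0, 24, 48], [98, 82, 66], unit="hours")
        fit = fit_linear_turnover(tc)
        assert fit.slope == pytest.approx(-16.0, abs=1e-9)

    def test_channel_symmetry(self, linear_tc):
        """Dred+ and Dred- fits mirror each other (conservation to 100%)."""
        plus = fit_linear_turnover(linear_tc)
        minus = fit_linear_turnover(linear_tc.complement())
        assert minus.slope == pytest.approx(-plus.slope, abs=1e-9)
        assert minus.intercept == pytest.approx(100 - plus.intercept, abs=1e-9)

    def test_slope_unbiased_under_replicate_noise(self):
        """Mean fitted slope over 1000 noisy series is within 2% of truth."""
        slopes = []
        for seed in range(1000):
            tc = gen_linear_photoconversion(noise=2.0, seed=seed, replicates=3)
            slopes.append(fit_linear_turnover(tc).slope)
        assert np.mean(slopes) == pytest.approx(-16.8, rel=0.02)

    @given(st.floats(min_value=1.0, max_value=30.0))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_t50_decreases_with_steeper_slope(self, rate):
        base = fit_linear_turnover(linear_series(98.7, -rate, (0, 1, 2, 3)))
        steeper = fit_linear_turnover(linear_series(98.7, -rate - 1, (0, 1, 2, 3)))
        assert steeper.t50 < base.t50

    def test_sklearn_estimator_contract(self):
        est = LinearTurnoverRegressor()
        t = np.array([[0.0], [1.0], [2.0]])
        est.fit(t, np.array([90.0, 80.0, 70.0]))
        np.testing.assert_allclose(est.predict(t), [90, 80, 70], atol=1e-9)
        assert est.get_params() == {}


class TestExponentialDecay:
    def test_recovers_generated_half_life(self):
        tc = as_timecourse([0, 4, 8, 12, 24],
                           [100 * 2 ** (-t / 10) for t in (0, 4, 8, 12, 24)],
                           unit="hours")
        fit = fit_exponential_decay(tc)
        assert fit.half_life == pytest.approx(10.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-6)
        assert fit.unit == "hours"

    def test_exact_halving_per_unit_time(self):
        fit = fit_exponential_decay(as_timecourse([0, 1, 2], [100, 50, 25]))
        assert fit.half_life == pytest.approx(1.0, rel=1e-6)
        assert fit.rate == pytest.approx(math.log(2), rel=1e-6)

    def test_recovers_printed_cd103_cdc2_half_life(self):
        """A 6.3 h half-life sampled away from t=0 is still recovered."""
        tc = gen_exponential_photoconversion(
            half_life=6.3, times=[4, 8, 12, 18, 24], noise=None)
        fit = fit_exponential_decay(tc)
        assert fit.half_life == pytest.approx(6.3, rel=1e-6)

    def test_requires_three_distinct_positive_points(self):
        with pytest.raises(InvalidInputError):
            fit_exponential_decay(as_timecourse([0, 1], [100, 50]))
        with pytest.raises(InvalidInputError):
            fit_exponential_decay(as_timecourse([0, 1, 2, 3], [100, 50, 0, 0]))


class TestReplacedFraction:
    def test_slowest_subset_exceeds_80_percent_in_a_day(self):
        fit = ExponentialDecayFit.from_half_life(10.1)
        value = replaced_fraction_at(fit, 24.0)
        assert value == pytest.approx(100 * (1 - 2 ** (-24 / 10.1)), abs=1e-9)
        assert value >= 80.0

    def test_boundary_values(self):
        fit = ExponentialDecayFit.from_half_life(7.0)
        assert replaced_fraction_at(fit, 0.0) == pytest.approx(0.0)
        assert replaced_fraction_at(fit, 7.0) == pytest.approx(50.0)

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            replaced_fraction_at(ExponentialDecayFit.from_half_life(7.0), -1.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_monotone_and_saturating(self, t):
        fit = ExponentialDecayFit.from_half_life(9.5)
        a, b = replaced_fraction_at(fit, t), replaced_fraction_at(fit, t + 1)
        assert 0 <= a < b < 100
        assert replaced_fraction_at(fit, 1e6) == pytest.approx(100.0)


class TestBrduEgress:
    def test_default_chase_matches_printed_rate(self):
        tc = as_timecourse([24, 48, 72], [20.0, 14.74, 9.48], unit="hours")
        est = estimate_egress_rate_brdu(tc)
        assert est.slope_pp_per_day == pytest.approx(5.26, abs=1e-9)
        assert est.peak_labelled_fraction == pytest.approx(20.0, abs=1e-9)
        assert est.egress_rate_percent_per_day == pytest.approx(26.3, abs=1e-9)
        assert est.physical

    def test_flat_chase_gives_zero_egress(self):
        est = estimate_egress_rate_brdu(
            as_timecourse([24, 48, 72], [15, 15, 15], unit="hours"))
        assert est.slope_pp_per_day == pytest.approx(0.0)
        assert est.egress_rate_percent_per_day == pytest.approx(0.0)

    def test_unit_ratio(self):
        est = estimate_egress_rate_brdu(
            as_timecourse([24, 48, 72], [10, 9, 8], unit="hours"))
        assert est.egress_rate_percent_per_day == pytest.approx(10.0, abs=1e-9)

    def test_increasing_fraction_flagged_non_physical(self):
        est = estimate_egress_rate_brdu(
            as_timecourse([24, 48, 72], [10, 12, 14], unit="hours"))
        assert not est.physical
        assert math.isnan(est.egress_rate_percent_per_day)

    def test_single_time_point_rejected(self):
        with pytest.raises(InvalidInputError):
            estimate_egress_rate_brdu(as_timecourse([24, 24], [20, 21],
                                                    unit="hours"))


class TestMaturationProfile:
    @pytest.mark.parametrize(
        "means, rise, drop",
        [
            ((2, 4, 6, 8, 1), True, True),
            ((5, 5, 5, 5, 5), True, False),
            ((3, 2, 4, 6, 1), False, True),
        ],
    )
    def test_pattern_flags(self, means, rise, drop):
        table = {b: [m] for b, m in zip(("M1", "M2", "M3", "M4", "CCR7+"), means)}
        prof = summarize_maturation_bins(table)
        assert prof.monotone_rise_m1_m4 is rise
        assert prof.drop_at_ccr7 is drop

    def test_means_average_replicates(self):
        table = {"M1": [1, 3], "M2": [4], "M3": [5], "M4": [6], "CCR7+": [2]}
        prof = summarize_maturation_bins(table)
        assert prof.means["M1"] == pytest.approx(2.0)

    def test_missing_bin_rejected(self):
        with pytest.raises(InvalidInputError, match="CCR7"):
            summarize_maturation_bins({"M1": [1], "M2": [2], "M3": [3], "M4": [4]})
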