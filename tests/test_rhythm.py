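"""Trace analytics: windowed means, extrema, period, amplitude, periodogram."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rreclock.rhythm import (
    Extrema,
    Trace,
    analyze_trace,
    chi_square_periodogram,
    detrend,
    estimate_area_amplitude,
    estimate_period,
    find_peaks_troughs,
    moving_average_smooth,
    relative_amplitude,
)
from rreclock.synthetic import gen_bioluminescence_trace, gen_wheel_activity


def _trace(values, dt=0.1):
    t = np.arange(len(values)) * dt
    return Trace(t, np.asarray(values, dtype=float))


def _brute_force_window_mean(trace, window):
    """Independent oracle: plain python mean over each full centered window."""
    half = int(round(window / (2 * trace.dt)))
    out_t, out_v = [], []
    for i in range(half, trace.times.size - half):
        out_t.append(trace.times[i])
        out_v.append(float(np.mean(trace.values[i - half : i + half + 1])))
    return np.array(out_t), np.array(out_v)


class TestMovingAverage:
    def test_constant_trace_unchanged_but_shorter(self):
        trace = _trace(np.full(100, 5.0))
        out = moving_average_smooth(trace, 2.0)
        assert np.allclose(out.values, 5.0)
        assert out.times.size == 100 - 2 * 10

    def test_linear_ramp_is_fixed_point(self):
        t = np.arange(0.0, 50.0, 0.1)
        trace = Trace(t, 1.5 + 0.3 * t)
        out = moving_average_smooth(trace, 2.0)
        assert np.allclose(out.values, 1.5 + 0.3 * out.times, atol=1e-10)

    def test_sinusoid_matches_brute_force_oracle(self):
        t = np.arange(0.0, 96.0, 0.1)
        trace = Trace(t, np.sin(2 * np.pi * t / 24.0))
        out = moving_average_smooth(trace, 2.0)
        oracle_t, oracle_v = _brute_force_window_mean(trace, 2.0)
        assert np.allclose(out.times, oracle_t)
        assert np.allclose(out.values, oracle_v, atol=1e-12)
        # windowed averaging attenuates the oscillation
        assert np.max(np.abs(out.values)) < 1.0

    def test_window_shorter_than_sampling_rejected(self):
        with pytest.raises(ValueError):
            moving_average_smooth(_trace(np.ones(10), dt=1.0), 0.5)


class TestDetrend:
    def test_pure_trend_vanishes(self):
        t = np.arange(0.0, 72.0, 0.25)
        out = detrend(Trace(t, 4.0 + 0.2 * t), 24.0)
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_24h_sinusoid_survives_with_trend_removed(self):
        t = np.arange(0.0, 120.0, 0.1)
        rhythm = np.sin(2 * np.pi * t / 24.0)
        out = detrend(Trace(t, rhythm + 3.0 + 0.1 * t), 24.0)
        # the 24-hr moving mean of a 24-hr sinusoid is ~0, so the rhythm stays
        expected = np.sin(2 * np.pi * out.times / 24.0)
        assert np.allclose(out.values, expected, atol=5e-3)

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 60.0, 0.5)
        trace = Trace(t, rng.normal(10.0, 2.0, t.size))
        out = detrend(trace, 24.0)
        oracle_t, oracle_mean = _brute_force_window_mean(trace, 24.0)
        half = (t.size - out.times.size) // 2
        assert np.allclose(out.times, oracle_t)
        assert np.allclose(
            out.values, trace.values[half:-half] - oracle_mean, atol=1e-12
        )

    def test_record_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            detrend(_trace(np.ones(50), dt=0.1), 24.0)


class TestPeaksTroughs:
    def test_cosine_peak_times(self):
        t = np.arange(0.0, 96.0, 0.1)
        peaks, troughs = find_peaks_troughs(Trace(t, np.cos(2 * np.pi * t / 24.0)))
        assert np.allclose(peaks.times, [24.0, 48.0, 72.0], atol=0.1)
        assert np.allclose(troughs.times, [12.0, 36.0, 60.0, 84.0], atol=0.1)

    def test_monotone_trace_has_no_extrema(self):
        t = np.arange(0.0, 48.0, 0.1)
        peaks, troughs = find_peaks_troughs(Trace(t, 0.1 * t))
        assert peaks.times.size == 0 and troughs.times.size == 0

    def test_alternation_after_reconciliation(self):
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 240.0, 0.1)
        v = np.cos(2 * np.pi * t / 24.0) + rng.normal(0, 0.05, t.size)
        peaks, troughs = find_peaks_troughs(Trace(t, v))
        events = sorted(
            [(tt, "p") for tt in peaks.times] + [(tt, "t") for tt in troughs.times]
        )
        kinds = [k for _, k in events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_mild_noise_does_not_add_peaks(self):
        """After the standard 2-hr smoothing, 5% noise leaves the count."""
        t = np.arange(0.0, 96.0, 0.1)
        clean = np.cos(2 * np.pi * t / 24.0)
        rng = np.random.default_rng(5)
        noisy = clean + rng.normal(0, 0.05, t.size)
        clean_peaks, _ = find_peaks_troughs(
            moving_average_smooth(Trace(t, clean), 2.0)
        )
        noisy_peaks, _ = find_peaks_troughs(
            moving_average_smooth(Trace(t, noisy), 2.0)
        )
        assert noisy_peaks.times.size == clean_peaks.times.size


class TestPeriodAndAmplitude:
    def test_first_three_extrema_rule(self):
        peaks = Extrema(np.array([10.0, 34.0, 58.0]), np.ones(3))
        troughs = Extrema(np.array([22.0, 46.0, 70.0]), -np.ones(3))
        assert estimate_period(peaks, troughs) == pytest.approx(24.0)
        # a 4th peak must be ignored
        peaks4 = Extrema(np.array([10.0, 34.0, 58.0, 82.5]), np.ones(4))
        assert estimate_period(peaks4, troughs) == pytest.approx(24.0)

    def test_insufficient_extrema_is_inconclusive(self):
        two = Extrema(np.array([1.0, 2.0]), np.ones(2))
        three = Extrema(np.array([1.0, 2.0, 3.0]), np.ones(3))
        assert estimate_period(two, three) is None

    def test_unit_sinusoid_mean_abs_is_2_over_pi(self):
        t = np.arange(0.0, 96.0, 0.01)
        det = Trace(t, np.sin(2 * np.pi * t / 24.0))
        peaks, troughs = find_peaks_troughs(det)
        area = estimate_area_amplitude(det, peaks, troughs)
        assert area == pytest.approx(2.0 / np.pi, abs=1e-3)

    def test_zero_trace_has_zero_area(self):
        t = np.arange(0.0, 96.0, 0.1)
        det = Trace(t, np.zeros(t.size))
        peaks = Extrema(np.array([24.0, 48.0]), np.zeros(2))
        troughs = Extrema(np.array([12.0, 36.0]), np.zeros(2))
        assert estimate_area_amplitude(det, peaks, troughs) == pytest.approx(0.0)

    def test_area_matches_quadrature_oracle(self):
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 120.0, 0.1)
        v = np.sin(2 * np.pi * t / 24.0) + 0.1 * rng.normal(size=t.size)
        det = Trace(t, v)
        peaks, troughs = find_peaks_troughs(det)
        area = estimate_area_amplitude(det, peaks, troughs)
        t0, t1 = troughs.times[0], peaks.times[1]
        m = (t >= t0) & (t <= t1)
        oracle = np.trapezoid(np.abs(v[m]), t[m]) / (t[m][-1] - t[m][0])
        assert area == pytest.approx(oracle, rel=1e-3)

    @pytest.mark.parametrize(
        "values, expected",
        [(np.full(10, 3.0), 0.0), (np.linspace(0.0, 2.0, 20), 1.0)],
    )
    def test_relative_amplitude_closed_forms(self, values, expected):
        assert relative_amplitude(_trace(values)) == pytest.approx(expected)

    def test_relative_amplitude_undefined_for_nonpositive(self):
        assert relative_amplitude(_trace(np.full(5, -1.0))) is None

    def test_sinusoid_relative_amplitude(self):
        t = np.arange(0.0, 48.0, 0.01)
        trace = Trace(t, 1.0 + 0.5 * np.sin(2 * np.pi * t / 24.0))
        assert relative_amplitude(trace) == pytest.approx(2.0 / 3.0, abs=1e-3)


class TestScaleAndShiftInvariance:
    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance(self, scale):
        trace, _ = gen_bioluminescence_trace(
            noise_sigma=0.1, duration=120.0, seed=21
        )
        base = analyze_trace(trace)
        scaled = analyze_trace(Trace(trace.times, trace.values * scale))
        assert scaled.period == pytest.approx(base.period, abs=1e-9)
        assert scaled.area_amplitude == pytest.approx(
            base.area_amplitude * scale, rel=1e-9
        )
        assert scaled.relative_amplitude == pytest.approx(
            base.relative_amplitude, rel=1e-9
        )

    def test_time_shift_leaves_period_unchanged(self):
        trace, _ = gen_bioluminescence_trace(
            noise_sigma=0.1, duration=120.0, seed=22
        )
        base = analyze_trace(trace)
        shifted = analyze_trace(Trace(trace.times + 13.0, trace.values))
        assert shifted.period == pytest.approx(base.period, abs=1e-9)


class TestChiSquarePeriodogram:
    def test_square_wave_argmax_at_24(self):
        activity, _ = gen_wheel_activity(free_running_period=24.0, days=14, seed=3)
        pgram = chi_square_periodogram(activity, (20.0, 28.0))
        assert pgram.best_period == pytest.approx(24.0, abs=activity.dt)

    def test_null_significance_fraction_matches_alpha(self):
        """On i.i.d. noise the chi-square calibration holds: the fraction of
        candidate periods called significant at alpha tracks alpha."""
        rng = np.random.default_rng(17)
        alpha = 0.01
        hits = total = 0
        for _ in range(20):
            t = np.arange(0.0, 14 * 24.0, 1.0 / 12.0)
            trace = Trace(t, rng.normal(10.0, 2.0, t.size))
            pgram = chi_square_periodogram(trace, (20.0, 28.0), alpha=alpha)
            hits += int(pgram.significant.sum())
            total += pgram.periods.size
        frac = hits / total
        assert frac == pytest.approx(alpha, abs=3 * np.sqrt(alpha / total) + 0.005)

    def test_grid_excluding_truth_picks_adjacent(self):
        activity, _ = gen_wheel_activity(free_running_period=24.0, days=14, seed=4)
        pgram = chi_square_periodogram(activity, (24.5, 28.0))
        assert pgram.best_period == pytest.approx(24.5, abs=activity.dt)

    def test_zero_variance_yields_nothing_significant(self):
        t = np.arange(0.0, 10 * 24.0, 1.0 / 12.0)
        pgram = chi_square_periodogram(Trace(t, np.full(t.size, 4.0)))
        assert pgram.best_period is None
        assert not np.any(pgram.significant)

    def test_qp_non_negative(self):
        activity, _ = gen_wheel_activity(days=10, seed=6)
        pgram = chi_square_periodogram(activity)
        assert np.all(pgram.qp[np.isfinite(pgram.qp)] >= 0)
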