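"""Rate-of-change, detrending, FFT periods, pulses and shifted correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edgepulse import oscillation as osc
from edgepulse.synthetic import pulse_train_rate


def _ts(values, dt=10.0, label=""):
    values = np.asarray(values, dtype=float)
    return osc.TimeSeries(times=np.arange(values.size) * dt, values=values, label=label)


class TestRateOfChange:
    def test_constant_series_has_zero_rate(self):
        rate = osc.rate_of_change(_ts(np.full(20, 7.0)))
        assert np.allclose(rate.rates, 0.0)
        assert rate.rates.size == 20 - 6  # minus lag/dt samples

    def test_linear_series_recovers_slope(self):
        t = np.arange(30) * 10.0
        rate = osc.rate_of_change(osc.TimeSeries(times=t, values=2.5 * t / 60.0))
        assert np.allclose(rate.rates, 2.5)

    def test_differenced_sinusoid_keeps_its_period(self):
        # x(t+L) - x(t) = 2 sin(pi L / P) cos(2pi(t + L/2)/P): same period P
        P, dt = 120.0, 10.0
        t = np.arange(0, 600, dt)
        rate = osc.rate_of_change(osc.TimeSeries(times=t, values=np.sin(2 * np.pi * t / P)))
        expected = 2 * np.sin(np.pi * 60 / P) * np.cos(2 * np.pi * (rate.times + 30) / P)
        assert np.allclose(rate.rates, expected, atol=1e-9)

    def test_non_multiple_lag_is_interpolated_and_flagged(self):
        rate = osc.rate_of_change(_ts(np.arange(30.0), dt=7.0), lag=60.0)
        assert rate.interpolated

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            osc.rate_of_change(_ts([1.0, 2.0], dt=10.0), lag=60.0)


class TestDetrend:
    def test_pure_line_maps_to_zero(self):
        t = np.arange(50) * 3.0
        out = osc.detrend(osc.TimeSeries(times=t, values=4.0 * t + 2.0))
        assert np.allclose(out.values, 0.0, atol=1e-9)

    def test_added_line_is_removed_exactly(self):
        # OLS is linear: detrend(x + line) == detrend(x) for any x
        P, dt = 126.0, 3.0
        t = np.arange(0, 630, dt)
        sinus = np.sin(2 * np.pi * t / P)
        out = osc.detrend(osc.TimeSeries(times=t, values=sinus + 0.3 * t - 5.0))
        ref = osc.detrend(osc.TimeSeries(times=t, values=sinus))
        assert np.allclose(out.values, ref.values, atol=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ts = _ts(rng.normal(size=40))
        once = osc.detrend(ts)
        twice = osc.detrend(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)


class TestDominantPeriod:
    @pytest.mark.parametrize("period,dt,duration", [(126.0, 3.0, 630.0), (130.0, 10.0, 650.0)])
    def test_binaligned_sinusoid_exact(self, period, dt, duration):
        t = np.arange(0, duration, dt)
        rate = osc.RateSignal(times=t, rates=np.sin(2 * np.pi * t / period))
        assert osc.dominant_period(osc.detrend(rate)) == period

    def test_dominant_of_mixture_by_brute_force_periodogram(self):
        dt = 5.0
        t = np.arange(0, 1000, dt)
        values = 2 * np.sin(2 * np.pi * t / 100) + 1 * np.sin(2 * np.pi * t / 50)
        # brute-force periodogram oracle over candidate frequencies
        freqs = np.fft.rfftfreq(t.size, dt)[1:]
        power = [
            np.abs(np.sum(values * np.exp(-2j * np.pi * f * t))) for f in freqs
        ]
        oracle = 1.0 / freqs[int(np.argmax(power))]
        est = osc.dominant_period(osc.detrend(osc.RateSignal(times=t, rates=values)))
        assert est == pytest.approx(oracle)
        assert est == pytest.approx(100.0)

    def test_amplitude_and_trend_invariance(self):
        dt = 10.0
        t = np.arange(0, 650, dt)
        base = np.sin(2 * np.pi * t / 130)
        p1 = osc.dominant_period(osc.detrend(osc.RateSignal(times=t, rates=base)))
        p2 = osc.dominant_period(
            osc.detrend(osc.RateSignal(times=t, rates=5.0 * base + 0.01 * t - 3))
        )
        assert p1 == p2

    def test_flat_signal_has_no_period(self):
        t = np.arange(8) * 10.0
        with pytest.raises(ValueError):
            osc.dominant_period(osc.detrend(osc.RateSignal(times=t, rates=0.2 * t + 1)))


class TestPulseStats:
    def test_raised_cosine_lobes_recover_generating_areas(self):
        """Alternating lobes sized to the measured mean pulses (772 nm
        elongation, 114 nm shortening) are recovered exactly."""
        areas = np.ravel(np.column_stack([np.full(5, 0.772), np.full(5, -0.114)]))
        rate = pulse_train_rate(areas, lobe_duration=60.0, dt=10.0)
        ps = osc.pulse_stats(rate)
        assert ps.n_elongation == ps.n_shortening == 5
        assert ps.mean_elongation * 1000 == pytest.approx(772.0, abs=1e-9)
        assert ps.mean_shortening * 1000 == pytest.approx(114.0, abs=1e-9)

    def test_square_wave_closed_form(self):
        # +a for T then -a for T, k cycles: k pulses per sign, area a*T each
        a, dt, samples_per_half, k = 0.6, 10.0, 6, 3
        rates = np.tile(np.r_[np.full(samples_per_half, a), np.full(samples_per_half, -a)], k)
        rate = osc.RateSignal(times=np.arange(rates.size) * dt, rates=rates)
        ps = osc.pulse_stats(rate)
        assert ps.n_elongation == ps.n_shortening == k
        area = a * samples_per_half * dt / 60.0
        assert ps.mean_elongation == pytest.approx(area)
        assert ps.mean_shortening == pytest.approx(area)

    def test_monotone_rise_is_one_elongation_pulse(self):
        rate = osc.RateSignal(times=np.arange(10) * 10.0, rates=np.full(10, 0.5))
        ps = osc.pulse_stats(rate)
        assert ps.n_elongation == 1 and ps.n_shortening == 0
        assert ps.mean_shortening is None

    def test_zero_samples_split_runs(self):
        rates = np.array([1.0, 1.0, 0.0, 1.0])
        ps = osc.pulse_stats(osc.RateSignal(times=np.arange(4) * 10.0, rates=rates))
        assert ps.n_elongation == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-2, 2), min_size=4, max_size=60), st.floats(1, 30))
    def test_conservation_identity(self, rates, dt):
        """total elongation − total shortening == Σ rate·dt (rectangle rule)."""
        rates = np.asarray(rates)
        sig = osc.RateSignal(times=np.arange(rates.size) * dt, rates=rates)
        ps = osc.pulse_stats(sig)
        assert ps.net_change == pytest.approx(np.sum(rates) * dt / 60.0, abs=1e-9)


class TestCorrelate:
    def test_self_and_negation(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        assert osc.correlate(a, a) == pytest.approx(1.0)
        assert osc.correlate(a, -a) == pytest.approx(-1.0)

    def test_seeded_draws_inside_fisher_interval(self):
        from edgepulse.synthetic import generate_correlated_pairs

        (a, b), = generate_correlated_pairs(1, 1, 0.6, 220, seed=5)
        r = osc.correlate(a, b)
        z = np.arctanh(-0.6)
        lo, hi = np.tanh(z - 1.96 / np.sqrt(217)), np.tanh(z + 1.96 / np.sqrt(217))
        assert lo <= r <= hi

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=30), rng.normal(size=30)
        r = osc.correlate(a, b)
        assert osc.correlate(3 * a + 7, b) == pytest.approx(r)
        assert osc.correlate(-a, b) == pytest.approx(-r)
        assert osc.correlate(b, a) == pytest.approx(r)

    def test_zero_variance_is_signalled(self):
        with pytest.raises(ValueError):
            osc.correlate(np.ones(10), np.arange(10.0))


class TestShiftScan:
    def test_self_correlation_peaks_at_zero(self):
        rng = np.random.default_rng(3)
        a = np.cumsum(rng.normal(size=120))
        curve = osc.shift_scan(a, a, dt=10.0)
        assert curve.shift_at_first_max == 0.0

    def test_antiphase_sinusoid_extrema(self):
        # b is a half a period (60 s) ahead: r(0) = -1, r(±60) = +1
        t = np.arange(0, 1200, 10.0)
        a = np.sin(2 * np.pi * t / 120)
        b = np.sin(2 * np.pi * (t + 60) / 120)
        curve = osc.shift_scan(a, b, dt=10.0)
        assert curve.shift_at_first_min == 0.0
        assert abs(curve.shift_at_first_max) == 60.0
        assert curve.tie_max  # ±60 s are equivalent; negative reported, flagged

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(4)
        a = np.cumsum(rng.normal(size=200))
        b = np.cumsum(rng.normal(size=200))
        ab = osc.shift_scan(a, b, dt=10.0)
        ba = osc.shift_scan(b, a, dt=10.0)
        assert np.allclose(ab.r_raw, ba.r_raw[::-1], atol=1e-12)

    def test_antiphase_population_min_closer_than_max(self):
        """For anti-correlated pairs, the |shift| to the first minimum is
        smaller than to the first maximum for the large majority."""
        from edgepulse.synthetic import generate_correlated_pairs

        pairs = generate_correlated_pairs(30, 30, 0.9, 90, seed=6)
        wins = 0
        for a, b in pairs:
            c = osc.shift_scan(a, b, dt=10.0)
            if c.shift_at_first_min is None or c.shift_at_first_max is None:
                continue
            if abs(c.shift_at_first_min) < abs(c.shift_at_first_max):
                wins += 1
        assert wins >= 24  # ≥ 80%

    def test_insufficient_overlap_raises(self):
        with pytest.raises(ValueError):
            osc.shift_scan(np.arange(10.0), np.arange(10.0), dt=30.0)
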