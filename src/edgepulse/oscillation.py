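"""Oscillation analysis of junction-length and apical-area signals.

The pipeline mirrors how pulsatile cell behaviours are quantified in
germband time-lapse data:

1. convert a measured series x(t) into a rate of change per minute, using
   differences of samples one minute apart: rate(t) = x(t + lag) − x(t),
   scaled to per-minute units;
2. detrend the rate by subtracting the ordinary-least-squares line;
3. estimate the oscillation period as the inverse of the dominant
   (non-DC) frequency of the FFT of the detrended rate;
4. decompose the rate into elongation pulses (contiguous runs of strictly
   positive rate) and shortening pulses (strictly negative runs), with the
   signed area under each run integrated by the rectangle rule so that
   total elongation − total shortening equals the net length change
   exactly;
5. relate paired signals by Pearson correlation, either at zero lag or by
   scanning time shifts of one signal against the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "RateSignal",
    "Pulse",
    "PulseSet",
    "ShiftCorrelationCurve",
    "rate_of_change",
    "detrend",
    "dominant_period",
    "pulse_stats",
    "correlate",
    "shift_scan",
]


@dataclass
class TimeSeries:
    """A uniformly sampled scalar series (times in s)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        d = np.diff(self.times)
        if d.size and (np.any(d <= 0) or not np.allclose(d, d[0])):
            raise ValueError("sampling must be uniform and strictly increasing")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("dt undefined for fewer than two samples")
        return float(self.times[1] - self.times[0])


@dataclass
class RateSignal:
    """Rate of change per minute, referenced to the earlier sample time."""

    times: np.ndarray
    rates: np.ndarray
    lag: float = 60.0
    label: str = ""
    interpolated: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.times.size != self.rates.size:
            raise ValueError("times and rates must have equal length")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("dt undefined for fewer than two samples")
        return float(self.times[1] - self.times[0])


@dataclass
class Pulse:
    """One contiguous run of same-sign rate samples."""

    start: float  # s, time of first sample in the run
    end: float  # s, time of last sample in the run
    sign: int  # +1 elongation, −1 shortening
    area: float  # unsigned magnitude, in the source signal's units (µm)


@dataclass
class PulseSet:
    """Pulse decomposition of a rate signal.

    Areas are unsigned magnitudes in source units (µm for length signals);
    ``mean_elongation``/``mean_shortening`` are ``None`` when no pulse of
    that sign exists.
    """

    pulses: list[Pulse]
    total_elongation: float
    total_shortening: float
    n_elongation: int
    n_shortening: int

    @property
    def mean_elongation(self) -> float | None:
        return self.total_elongation / self.n_elongation if self.n_elongation else None

    @property
    def mean_shortening(self) -> float | None:
        return self.total_shortening / self.n_shortening if self.n_shortening else None

    @property
    def net_change(self) -> float:
        """total elongation − total shortening (signed net length change)."""
        return self.total_elongation - self.total_shortening


@dataclass
class ShiftCorrelationCurve:
    """Time-shifted correlation between two signals.

    Positive shift means the first signal is delayed relative to the
    second.  ``shift_at_first_min``/``max`` are the extrema of the smoothed
    curve closest to zero shift; curve boundary points are not eligible.
    """

    shifts: np.ndarray  # s
    r_raw: np.ndarray
    r_smoothed: np.ndarray
    shift_at_first_min: float | None
    shift_at_first_max: float | None
    tie_min: bool = False
    tie_max: bool = False
    meta: dict = field(default_factory=dict)


def rate_of_change(ts: TimeSeries, lag: float = 60.0) -> RateSignal:
    """Difference of samples ``lag`` seconds apart, expressed per minute.

    rate(t) = (x(t + lag) − x(t)) · (60 / lag).  With the default 60-s lag
    the difference already is the per-minute change.  When ``lag`` is not a
    multiple of the sampling interval the later sample is obtained by
    linear interpolation and the result is flagged.
    """
    if lag <= 0:
        raise ValueError("lag must be positive")
    dt = ts.dt
    n = ts.values.size
    if lag >= ts.times[-1] - ts.times[0]:
        raise ValueError(
            f"trace spans {ts.times[-1] - ts.times[0]:g} s, shorter than lag {lag:g} s"
        )
    ratio = lag / dt
    k = int(round(ratio))
    interpolated = not np.isclose(ratio, k)
    if interpolated:
        shifted_times = ts.times + lag
        ok = shifted_times <= ts.times[-1] + 1e-9
        later = np.interp(shifted_times[ok], ts.times, ts.values)
        rates = (later - ts.values[ok]) * (60.0 / lag)
        times = ts.times[ok]
    else:
        rates = (ts.values[k:] - ts.values[:-k]) * (60.0 / lag)
        times = ts.times[:-k]
    return RateSignal(times=times, rates=rates, lag=lag, label=ts.label, interpolated=interpolated)


def _as_arrays(sig: TimeSeries | RateSignal) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(sig, RateSignal):
        return sig.times, sig.rates
    return sig.times, sig.values


def detrend(sig: TimeSeries | RateSignal):
    """Subtract the ordinary-least-squares line of best fit.

    Returns the same container type; the output has zero mean and zero
    linear trend, and the operation is idempotent.
    """
    times, values = _as_arrays(sig)
    if values.size < 2:
        raise ValueError("need at least two samples to detrend")
    slope, intercept = np.polyfit(times, values, 1)
    resid = values - (slope * times + intercept)
    if isinstance(sig, RateSignal):
        return RateSignal(times=times, rates=resid, lag=sig.lag, label=sig.label,
                          interpolated=sig.interpolated)
    return TimeSeries(times=times, values=resid, label=sig.label)


def dominant_period(sig: TimeSeries | RateSignal) -> float:
    """Inverse of the dominant non-DC frequency of the signal's FFT, in s.

    The signal should be detrended first (see :func:`detrend`); a signal
    that is identically zero carries no period and raises.  For a
    bin-aligned sinusoid of period P sampled over an integer number of
    cycles the estimate is exact.
    """
    times, values = _as_arrays(sig)
    if values.size < 4:
        raise ValueError("need at least 4 samples for a period estimate")
    dt = times[1] - times[0]
    if np.max(np.abs(values)) <= 1e-10:
        raise ValueError("signal has no oscillatory content after detrending")
    spectrum = np.abs(np.fft.rfft(values))
    spectrum[0] = 0.0  # DC carries no period
    freqs = np.fft.rfftfreq(values.size, d=dt)
    k = int(np.argmax(spectrum))
    return float(1.0 / freqs[k])


def pulse_stats(rate: RateSignal, dt: float | None = None) -> PulseSet:
    """Decompose a rate signal into elongation and shortening pulses.

    A pulse is a maximal run of strictly positive (elongation) or strictly
    negative (shortening) rate samples; zero samples belong to no pulse.
    The area of a run is Σ rate·dt by the rectangle rule, converted from
    (units/min)·s to source units, so that over the whole signal
    total elongation − total shortening equals the net change exactly.
    """
    if dt is None:
        dt = rate.dt
    r = rate.rates
    signs = np.sign(r).astype(int)
    pulses: list[Pulse] = []
    i = 0
    n = r.size
    while i < n:
        s = signs[i]
        if s == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and signs[j + 1] == s:
            j += 1
        area = float(np.sum(r[i : j + 1]) * dt / 60.0)  # (units/min)·s → units
        pulses.append(
            Pulse(start=float(rate.times[i]), end=float(rate.times[j]), sign=s, area=abs(area))
        )
        i = j + 1
    pos = [p for p in pulses if p.sign > 0]
    neg = [p for p in pulses if p.sign < 0]
    return PulseSet(
        pulses=pulses,
        total_elongation=float(sum(p.area for p in pos)),
        total_shortening=float(sum(p.area for p in neg)),
        n_elongation=len(pos),
        n_shortening=len(neg),
    )


def correlate(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("signals must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a zero-variance signal")
    return float(np.corrcoef(a, b)[0, 1])


def _smooth(values: np.ndarray, sigma_pts: float) -> np.ndarray:
    """Gaussian smoothing, kernel truncated at ±3σ with edge renormalization."""
    radius = max(1, int(np.ceil(3 * sigma_pts)))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma_pts) ** 2)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def _first_extremum(shifts: np.ndarray, y: np.ndarray, kind: str) -> tuple[float | None, bool]:
    """Interior local extremum of y with the smallest |shift|.

    Ties between a negative and a positive shift of equal magnitude report
    the negative shift and set the tie flag.
    """
    cand = []
    for i in range(1, y.size - 1):
        if kind == "min" and y[i] < y[i - 1] and y[i] < y[i + 1]:
            cand.append(shifts[i])
        if kind == "max" and y[i] > y[i - 1] and y[i] > y[i + 1]:
            cand.append(shifts[i])
    if not cand:
        return None, False
    cand = np.asarray(cand)
    best = np.min(np.abs(cand))
    hits = cand[np.isclose(np.abs(cand), best)]
    tie = hits.size > 1
    return float(np.min(hits)), tie


def shift_scan(
    a: np.ndarray,
    b: np.ndarray,
    dt: float,
    step: float = 10.0,
    max_shift: float = 240.0,
    sigma: float = 10.0,
) -> ShiftCorrelationCurve:
    """Correlation of two signals as one is shifted in time against the other.

    The first signal is shifted in increments of ``step`` seconds up to
    ``max_shift`` in both directions; at each shift the Pearson r is taken
    over the overlapping samples only (no zero padding, which would bias r
    toward 0).  The curve is Gaussian-smoothed (σ = ``sigma`` s, truncated
    at ±3σ, renormalized at the boundaries) before the extrema closest to
    zero shift are located.

    Sign convention: a positive shift delays signal ``a`` (e.g. edge
    length) relative to ``b``, so ``shift_scan(a, b)`` evaluated at +s
    equals ``shift_scan(b, a)`` at −s.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("signals must have equal length")
    shifts = np.arange(-max_shift, max_shift + step / 2, step)
    ks = np.round(shifts / dt).astype(int)
    n = a.size
    r_raw = np.empty(shifts.size)
    for idx, k in enumerate(ks):
        if k >= 0:
            xa, xb = a[: n - k] if k else a, b[k:] if k else b
        else:
            xa, xb = a[-k:], b[: n + k]
        if xa.size < 3:
            raise ValueError(
                f"only {xa.size} overlapping samples at shift {shifts[idx]:g} s; need ≥ 3"
            )
        r_raw[idx] = correlate(xa, xb)
    r_smoothed = _smooth(r_raw, sigma / step)
    smin, tie_min = _first_extremum(shifts, r_smoothed, "min")
    smax, tie_max = _first_extremum(shifts, r_smoothed, "max")
    return ShiftCorrelationCurve(
        shifts=shifts,
        r_raw=r_raw,
        r_smoothed=r_smoothed,
        shift_at_first_min=smin,
        shift_at_first_max=smax,
        tie_min=tie_min,
        tie_max=tie_max,
        meta={
            "sign_convention": "positive shift delays the first signal relative to the second",
            "step_s": step,
            "max_shift_s": max_shift,
            "sigma_s": sigma,
            "exact_sample_shifts": bool(np.allclose(shifts / dt, ks)),
        },
    )
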