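"""Circadian time-series metrics for bioluminescence-like traces.

The processing chain mirrors standard luminometer practice: raw traces are
smoothed with a 2-hr centered moving average, detrended by subtracting a
24-hr centered moving average, and peaks/troughs of the detrended signal
give the period (mean of the first three inter-peak and inter-trough
intervals) and an area-based amplitude (mean |detrended| between the first
trough and the second peak).  Locomotor-activity records binned in counts
are scanned with a Sokolove-Bushell chi-square periodogram.

Edge samples where a full centered window does not fit are dropped, so
smoothing and detrending shorten the record.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import signal, stats


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled time series (times in hr)."""

    times: np.ndarray
    values: np.ndarray
    label: str | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size < 2 or t.size != v.size:
            raise ValueError("trace needs >= 2 aligned samples")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValueError("sampling interval must be uniform")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_hr": self.times, "value": self.values})


def read_trace(path: str | Path, label: str | None = None) -> Trace:
    df = pd.read_csv(path)
    return Trace(df["time_hr"].to_numpy(), df["value"].to_numpy(), label)


def write_trace(trace: Trace, path: str | Path) -> None:
    trace.to_frame().to_csv(path, index=False)


class Extrema(NamedTuple):
    times: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class RhythmSummary:
    peaks: Extrema
    troughs: Extrema
    period: float | None  # hr
    area_amplitude: float | None  # signal units
    relative_amplitude: float | None


def _centered_window(trace: Trace, window: float) -> int:
    """Half-width in samples of a centered window of the given duration."""
    if window < trace.dt:
        raise ValueError(
            f"window ({window} hr) shorter than sampling interval ({trace.dt} hr)"
        )
    return int(round(window / (2.0 * trace.dt)))


def moving_average_smooth(trace: Trace, window: float = 2.0) -> Trace:
    """Centered moving mean; edge samples without a full window are dropped."""
    half = _centered_window(trace, window)
    if half == 0:
        return trace
    k = 2 * half + 1
    if trace.times.size < k:
        raise ValueError("trace shorter than the smoothing window")
    sw = np.lib.stride_tricks.sliding_window_view(trace.values, k)
    return Trace(trace.times[half:-half], sw.mean(axis=1), trace.label)


def detrend(trace: Trace, window: float = 24.0) -> Trace:
    """Subtract a centered moving average (default 24 hr); edges dropped."""
    span = trace.times[-1] - trace.times[0]
    if span <= window:
        raise ValueError(
            f"record ({span:g} hr) must be longer than the detrend window"
        )
    half = _centered_window(trace, window)
    k = 2 * half + 1
    sw = np.lib.stride_tricks.sliding_window_view(trace.values, k)
    center = trace.values[half:-half]
    return Trace(trace.times[half:-half], center - sw.mean(axis=1), trace.label)


def find_peaks_troughs(
    trace: Trace,
    min_separation: float = 12.0,
    min_prominence: float | None = None,
) -> tuple[Extrema, Extrema]:
    """Alternating local maxima and minima of a (detrended) trace.

    Prominence defaults to 10% of the trace maximum; after detection,
    consecutive same-type extrema are reconciled by keeping the more extreme
    one so that peaks and troughs strictly alternate in time.
    """
    v = trace.values
    if min_prominence is None:
        vmax = float(np.max(np.abs(v)))
        min_prominence = 0.1 * vmax if vmax > 0 else 0.0
    distance = max(1, int(round(min_separation / trace.dt)))
    kw = {"distance": distance}
    if min_prominence > 0:
        kw["prominence"] = min_prominence
    ipk, _ = signal.find_peaks(v, **kw)
    itr, _ = signal.find_peaks(-v, **kw)

    events = sorted(
        [(i, +1) for i in ipk] + [(i, -1) for i in itr]
    )
    kept: list[tuple[int, int]] = []
    for i, kind in events:
        if kept and kept[-1][1] == kind:
            j, _ = kept[-1]
            better = i if kind * v[i] > kind * v[j] else j
            kept[-1] = (better, kind)
        else:
            kept.append((i, kind))
    pk = np.array([i for i, kind in kept if kind > 0], dtype=int)
    tr = np.array([i for i, kind in kept if kind < 0], dtype=int)
    return (
        Extrema(trace.times[pk], v[pk]),
        Extrema(trace.times[tr], v[tr]),
    )


def estimate_period(peaks: Extrema, troughs: Extrema) -> float | None:
    """Mean of the first-three-peaks and first-three-troughs intervals.

    Uses exactly 4 intervals (2 inter-peak, 2 inter-trough); extra extrema
    are ignored.  Returns None when fewer than 3 of either are available.
    """
    if len(peaks.times) < 3 or len(troughs.times) < 3:
        return None
    intervals = np.concatenate(
        [np.diff(peaks.times[:3]), np.diff(troughs.times[:3])]
    )
    return float(intervals.mean())


def estimate_area_amplitude(
    detrended: Trace, peaks: Extrema, troughs: Extrema
) -> float | None:
    """Mean |detrended signal| from the first trough to the second peak."""
    if len(peaks.times) < 2 or len(troughs.times) < 2:
        return None
    t0, t1 = float(troughs.times[0]), float(peaks.times[1])
    if t1 <= t0:
        return None
    m = (detrended.times >= t0) & (detrended.times <= t1)
    t, v = detrended.times[m], np.abs(detrended.values[m])
    return float(np.trapezoid(v, t) / (t[-1] - t[0]))


def relative_amplitude(trace: Trace) -> float | None:
    """(max - min) / max; None when the maximum is not positive."""
    vmax = float(np.max(trace.values))
    if vmax <= 0:
        return None
    return (vmax - float(np.min(trace.values))) / vmax


def analyze_trace(
    trace: Trace,
    smooth_window: float = 2.0,
    detrend_window: float = 24.0,
    min_separation: float = 12.0,
) -> RhythmSummary:
    """Full smoothing -> detrending -> extrema -> period/amplitude chain."""
    smoothed = moving_average_smooth(trace, smooth_window)
    det = detrend(smoothed, detrend_window)
    peaks, troughs = find_peaks_troughs(det, min_separation)
    return RhythmSummary(
        peaks=peaks,
        troughs=troughs,
        period=estimate_period(peaks, troughs),
        area_amplitude=estimate_area_amplitude(det, peaks, troughs),
        relative_amplitude=relative_amplitude(trace),
    )


@dataclass(frozen=True)
class Periodogram:
    """Chi-square periodogram over a candidate period grid."""

    periods: np.ndarray  # hr
    qp: np.ndarray
    pvalues: np.ndarray
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        return self.pvalues < self.alpha

    @property
    def best_period(self) -> float | None:
        """Candidate with the largest Qp among significant periods."""
        if not np.any(self.significant):
            return None
        qp = np.where(self.significant, self.qp, -np.inf)
        return float(self.periods[int(np.argmax(qp))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"period_hr": self.periods, "Qp": self.qp, "p_value": self.pvalues}
        )


def chi_square_periodogram(
    activity: Trace,
    period_range: tuple[float, float] = (20.0, 28.0),
    alpha: float = 0.001,
) -> Periodogram:
    """Sokolove-Bushell chi-square periodogram of binned activity counts.

    Each candidate period P folds the record into K = round(P / dt) columns
    (truncated to complete rows).  The statistic

        Qp = N * Var(column means) / Var(all data)

    (population variances over the N folded samples) is chi-square
    distributed with K - 1 degrees of freedom under an arrhythmic null.
    A zero-variance record yields all-NaN Qp and no significant period.
    """
    dt = activity.dt
    v = activity.values
    lo, hi = period_range
    ks = np.arange(int(np.ceil(lo / dt)), int(np.floor(hi / dt)) + 1)
    if ks.size == 0:
        raise ValueError("period range contains no candidate periods")
    periods = ks * dt
    qp = np.full(ks.size, np.nan)
    pvals = np.ones(ks.size)
    total_var_ok = float(np.var(v)) > 0
    for j, k in enumerate(ks):
        rows = v.size // k
        if rows < 2:
            continue
        folded = v[: rows * k].reshape(rows, k)
        var_all = float(np.var(folded))
        if not total_var_ok or var_all == 0:
            continue
        col_means = folded.mean(axis=0)
        q = folded.size * float(np.var(col_means)) / var_all
        qp[j] = q
        pvals[j] = float(stats.chi2.sf(q, k - 1))
    if not total_var_ok:
        pvals = np.ones(ks.size)
    return Periodogram(periods, qp, pvals, alpha)
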