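"""Event-wise cross-correlation of neural activity and body bending.

Traces are smoothed with a 10-frame running average; individual bending
events are the segments of the (smoothed) angle trace between two consecutive
local minima, i.e. single undulation periods.  Within each event the two
signals are cross-correlated at integer lags up to +-100 steps of a 10
samples/s analysis grid (a +-10 s lag span); traces sampled at other rates
are linearly resampled to 10 Hz first.  The per-lag value is the Pearson
correlation of the lag-shifted overlapping samples, so every reported value
lies in [-1, 1].  Correlograms are aggregated across events as mean +- SEM,
and the signed peak is the value of largest magnitude inside a 5 s window
centred on the peak lag of a control mean correlogram.  Sign convention:
positive lag means the first signal leads the second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .segmentation import moving_average

__all__ = [
    "BendingEvent",
    "EventSet",
    "CorrelogramSet",
    "preprocess",
    "segment_events",
    "xcorr_events",
    "peak_correlation",
    "select_reversals",
    "ANALYSIS_RATE_HZ",
]

ANALYSIS_RATE_HZ = 10.0


def preprocess(trace: np.ndarray, smooth_frames: int = 10) -> np.ndarray:
    """Centred moving average over ``smooth_frames``, truncated at the ends."""
    trace = np.asarray(trace, dtype=float)
    if len(trace) <= smooth_frames:
        raise InputError(
            f"trace length {len(trace)} <= smoothing window {smooth_frames}")
    return moving_average(trace, smooth_frames)


@dataclass(frozen=True)
class BendingEvent:
    """One undulation period: sample indices of two consecutive angle minima."""

    start: int
    end: int


@dataclass
class EventSet:
    events: list[BendingEvent]
    n_dropped: int          # events shorter than the minimum duration
    fps: float

    def __len__(self) -> int:
        return len(self.events)


def segment_events(angle_trace: np.ndarray, fps: float,
                   prominence: float | None = None,
                   min_duration_s: float = 1.0) -> EventSet:
    """Delimit bending events by consecutive local minima of the angle trace.

    ``prominence`` defaults to 10% of the trace's peak-to-peak range.  Events
    shorter than ``min_duration_s`` are dropped and counted.  Fewer than two
    minima yield an empty (reported, not raised) event set.
    """
    from scipy.signal import find_peaks

    x = np.asarray(angle_trace, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size < 3 or np.ptp(finite) == 0:
        return EventSet(events=[], n_dropped=0, fps=fps)
    if prominence is None:
        prominence = 0.1 * np.ptp(finite)
    minima, _ = find_peaks(-np.nan_to_num(x, nan=-np.inf), prominence=prominence)
    events, dropped = [], 0
    for a, b in zip(minima[:-1], minima[1:]):
        if (b - a) / fps < min_duration_s:
            dropped += 1
        else:
            events.append(BendingEvent(int(a), int(b)))
    return EventSet(events=events, n_dropped=dropped, fps=fps)


@dataclass
class CorrelogramSet:
    lags_s: np.ndarray            # (2*max_lags + 1,)
    per_event: np.ndarray         # (n_events, n_lags); NaN where no overlap
    mean: np.ndarray
    sem: np.ndarray
    n_events: int
    peak_value: float = field(init=False)
    peak_lag_s: float = field(init=False)

    def __post_init__(self):
        self.peak_value, self.peak_lag_s = _signed_peak(self.lags_s, self.mean)


def _signed_peak(lags_s: np.ndarray, values: np.ndarray,
                 window: np.ndarray | None = None) -> tuple[float, float]:
    """Largest-magnitude value (sign preserved).

    Exact magnitude ties (periodic noise-free signals tie the peak and the
    half-period trough at +-1) are broken by preferring the positive value,
    then the smallest |lag|.
    """
    mask = ~np.isnan(values)
    if window is not None:
        mask &= window
    if not mask.any():
        return np.nan, np.nan
    mag = np.where(mask, np.abs(values), -np.inf)
    best = mag.max()
    tied = np.where(mag >= best - 1e-12)[0]
    pos = tied[values[tied] > 0]
    cands = pos if pos.size else tied
    idx = cands[np.argmin(np.abs(lags_s[cands]))]
    return float(values[idx]), float(lags_s[idx])


def _resample(trace: np.ndarray, fps: float, rate_hz: float) -> np.ndarray:
    if fps == rate_hz:
        return np.asarray(trace, dtype=float)
    t_old = np.arange(len(trace)) / fps
    t_new = np.arange(0.0, t_old[-1] + 0.5 / rate_hz, 1.0 / rate_hz)
    return np.interp(t_new, t_old, np.asarray(trace, dtype=float))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2:
        return np.nan
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def xcorr_events(events: EventSet, signal_a: np.ndarray, signal_b: np.ndarray,
                 max_lags: int = 100, rate_hz: float = ANALYSIS_RATE_HZ,
                 min_overlap: int = 10) -> CorrelogramSet:
    """Per-event normalized cross-correlograms over integer lags -N..+N.

    Positive lag means ``signal_a`` leads ``signal_b`` (the correlation at lag
    +k compares a(t) with b(t + k/rate)).  Both signals and the event
    boundaries are resampled to ``rate_hz``; a lag leaving fewer than
    ``min_overlap`` overlapping samples inside an event (default 1 s worth; a
    Pearson over two or three points is always near +-1 and carries no
    information) is missing for that event.
    """
    if len(events) == 0:
        raise InputError("no bending events to correlate")
    if len(signal_a) != len(signal_b):
        raise InputError("signals must have equal length")
    a = _resample(signal_a, events.fps, rate_hz)
    b = _resample(signal_b, events.fps, rate_hz)
    scale = rate_hz / events.fps

    lags = np.arange(-max_lags, max_lags + 1)
    per_event = np.full((len(events), len(lags)), np.nan)
    for e_i, ev in enumerate(events.events):
        s = int(round(ev.start * scale))
        e = min(int(round(ev.end * scale)) + 1, len(a))
        ea, eb = a[s:e], b[s:e]
        n = len(ea)
        for l_i, k in enumerate(lags):
            if n - abs(k) < max(min_overlap, 2):
                continue
            if k >= 0:
                seg_a, seg_b = ea[:n - k], eb[k:]
            else:
                seg_a, seg_b = ea[-k:], eb[:n + k]
            per_event[e_i, l_i] = _pearson(seg_a, seg_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(per_event, axis=0)
        counts = (~np.isnan(per_event)).sum(axis=0)
        sd = np.nanstd(per_event, axis=0, ddof=1)
    sem = np.where(counts > 1, sd / np.sqrt(np.maximum(counts, 1)), np.nan)
    return CorrelogramSet(lags_s=lags / rate_hz, per_event=per_event,
                          mean=mean, sem=sem, n_events=len(events))


def peak_correlation(cset: CorrelogramSet, control: CorrelogramSet,
                     window_s: float = 5.0) -> tuple[float, float]:
    """Signed peak of ``cset`` inside a window centred on the control's peak.

    Returns ``(value, lag_s)`` of the largest-magnitude mean correlation
    (sign preserved) within ``window_s`` seconds centred on the peak lag of
    the control mean correlogram; the window is clipped (with a warning) where
    it leaves the lag grid.
    """
    centre = control.peak_lag_s
    lo, hi = centre - window_s / 2, centre + window_s / 2
    if lo < cset.lags_s[0] or hi > cset.lags_s[-1]:
        warnings.warn("peak window extends beyond the lag grid; clipping",
                      stacklevel=2)
    window = (cset.lags_s >= lo) & (cset.lags_s <= hi)
    return _signed_peak(cset.lags_s, cset.mean, window)


def select_reversals(state: np.ndarray, fps: float,
                     min_duration_s: float = 10.0) -> list[tuple[int, int]]:
    """Maximal runs of 'reverse' frames lasting at least ``min_duration_s``.

    Returns half-open frame-index ranges ``(start, end)``; shorter reversal
    runs are excluded.
    """
    is_rev = np.asarray(state) == "reverse"
    if not is_rev.any():
        return []
    padded = np.concatenate([[False], is_rev, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return [(int(s), int(e)) for s, e in zip(starts, ends)
            if (e - s) / fps >= min_duration_s]
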