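"""Track-level quality control and windowed statistics.

A crawling track is a per-frame table of time, centroid position and body
length.  Frames are discarded when the (smoothed) centroid speed exceeds
1.25 mm/s — faster than a worm can crawl, so such frames are tracker errors —
or when the length deviates more than 25% from its baseline, the mean over
the first five seconds.  A video is excluded outright when more than 15% of
its frames had to be discarded (exactly 15% does not exclude).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BaselineError, InputError, ProtocolError
from .segmentation import moving_average

__all__ = [
    "QCReport",
    "compute_speed",
    "filter_track",
    "window_stats",
    "SPEED_CAP_MM_S",
    "LENGTH_TOLERANCE",
    "EXCLUSION_FRACTION",
]

SPEED_CAP_MM_S = 1.25
LENGTH_TOLERANCE = 0.25
EXCLUSION_FRACTION = 0.15


@dataclass
class QCReport:
    n_frames: int
    n_discarded: int
    video_excluded: bool
    reasons: list[str] = field(repr=False, default_factory=list)

    @property
    def discard_fraction(self) -> float:
        return self.n_discarded / self.n_frames if self.n_frames else 0.0


def compute_speed(track: pd.DataFrame, smooth_window_frames: int = 15) -> np.ndarray:
    """Centroid speed (mm/s) per frame, centred-moving-average smoothed.

    Speed at frame i is the displacement from frame i-1 times fps; the first
    frame repeats the second so the trace has full length.
    """
    t = track["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise InputError("need at least 2 frames to compute speed")
    if not np.all(np.diff(t) > 0):
        raise InputError("time_s must be strictly increasing")
    xy = track[["x_mm", "y_mm"]].to_numpy(dtype=float)
    step = np.linalg.norm(np.diff(xy, axis=0), axis=1) / np.diff(t)
    speed = np.concatenate([[step[0]], step])
    if smooth_window_frames > 1:
        speed = moving_average(speed, smooth_window_frames)
    return speed


def filter_track(track: pd.DataFrame, speed_cap: float = SPEED_CAP_MM_S,
                 length_tol: float = LENGTH_TOLERANCE,
                 exclusion_fraction: float = EXCLUSION_FRACTION,
                 baseline_s: float = 5.0,
                 smooth_window_frames: int = 15) -> tuple[pd.DataFrame, QCReport]:
    """Apply the speed and length-discrepancy filters and the 15% exclusion rule.

    Returns a copy of the track with added ``speed_mm_s``, ``valid`` and
    ``reason`` columns, plus a :class:`QCReport`.  The length baseline L0 is
    the mean length over the valid frames of the first ``baseline_s`` seconds.
    Filtering is idempotent: re-filtering an already filtered track discards
    nothing new.
    """
    t = track["time_s"].to_numpy(dtype=float)
    if t[-1] - t[0] < baseline_s:
        raise BaselineError(
            f"track spans {t[-1] - t[0]:.2f} s < {baseline_s} s baseline")
    out = track.copy()
    speed = compute_speed(track, smooth_window_frames)
    out["speed_mm_s"] = speed

    prior_valid = track["valid"].to_numpy(dtype=bool) if "valid" in track else \
        np.ones(len(track), dtype=bool)
    length = track["length_mm"].to_numpy(dtype=float)
    base_mask = (t - t[0] < baseline_s) & prior_valid & ~np.isnan(length)
    if not base_mask.any():
        raise BaselineError("no valid frames in the first 5 s for the baseline")
    L0 = length[base_mask].mean()

    too_fast = speed > speed_cap
    with np.errstate(invalid="ignore"):
        bad_length = np.abs(length - L0) / L0 > length_tol
    bad_length |= np.isnan(length)

    reasons = np.full(len(track), "", dtype=object)
    reasons[bad_length] = "length"
    reasons[too_fast] = "speed"
    reasons[too_fast & bad_length] = "speed+length"
    reasons[~prior_valid] = "prior"
    valid = prior_valid & ~too_fast & ~bad_length
    out["valid"] = valid
    out["reason"] = reasons

    n_disc = int((~valid & prior_valid).sum())
    report = QCReport(
        n_frames=int(prior_valid.sum()),
        n_discarded=n_disc,
        video_excluded=bool(n_disc / max(int(prior_valid.sum()), 1)
                            > exclusion_fraction),
        reasons=list(reasons),
    )
    return out, report


def window_stats(time_s: np.ndarray, trace: np.ndarray,
                 windows: dict[str, tuple[float, float]],
                 valid: np.ndarray | None = None) -> pd.DataFrame:
    """Mean and SEM of the valid samples inside each named time window.

    SEM uses the n-1 denominator; a window with no valid samples is reported
    with NaN mean/SEM and n = 0, never as zero.
    """
    time_s = np.asarray(time_s, dtype=float)
    trace = np.asarray(trace, dtype=float)
    mask = np.ones(len(trace), dtype=bool) if valid is None else \
        np.asarray(valid, dtype=bool)
    mask &= ~np.isnan(trace)
    rows = []
    for name, (t0, t1) in windows.items():
        if t0 > time_s[-1] or t1 < time_s[0]:
            raise ProtocolError(f"window '{name}' ({t0}, {t1}) outside the trace")
        m = mask & (time_s >= t0) & (time_s <= t1)
        n = int(m.sum())
        if n == 0:
            rows.append((name, np.nan, np.nan, 0))
        else:
            vals = trace[m]
            sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
            rows.append((name, float(vals.mean()), float(sem), n))
    return pd.DataFrame(rows, columns=["window", "mean", "sem", "n"])
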