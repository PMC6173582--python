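"""ROI fluorescence extraction and trace normalization.

Raw trace values are per-frame means over a signal ROI minus the mean over an
equal-size background ROI (background subtraction must precede normalization:
Delta F/F is scale- but not offset-invariant).  Single-channel traces are
normalized as ``dF/F = (F_i - F) / F`` with F the average of the entire
corrected trace; ratiometric (FRET cameleon) traces as ``dR/R = (R_i - R)/R``
on the per-frame YFP/CFP ratio, whose normalization span may be the full
trace or a stimulation window.  Multi-ROI sets can be aligned in time to the
first detected peak of a reference trace (e.g. the first dorsal Ca2+ spike).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import GeometryError, NormalizationError, RatioError

__all__ = [
    "Trace",
    "RatioTrace",
    "extract_roi_trace",
    "delta_f_over_f",
    "delta_r_over_r",
    "align_to_first_peak",
]


@dataclass
class Trace:
    time_s: np.ndarray
    corrected: np.ndarray                 # ROI mean minus background mean
    raw: np.ndarray | None = None
    background: np.ndarray | None = None
    normalized: np.ndarray | None = None  # dF/F once computed
    roi: str = ""
    channel: str = ""


@dataclass
class RatioTrace:
    time_s: np.ndarray
    ratio: np.ndarray                     # YFP/CFP per frame
    normalized: np.ndarray                # dR/R
    yfp: np.ndarray
    cfp: np.ndarray


def extract_roi_trace(stack: np.ndarray, roi_mask: np.ndarray,
                      background_mask: np.ndarray, fps: float,
                      roi: str = "", channel: str = "",
                      area_tol_px: int = 1) -> Trace:
    """Background-corrected mean-intensity trace of one ROI.

    Both masks must lie inside the frame and have equal pixel area within
    ``area_tol_px`` (matching background region size is what makes the
    subtraction an unbiased offset estimate).
    """
    stack = np.asarray(stack)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if roi_mask.shape != stack.shape[1:] or background_mask.shape != stack.shape[1:]:
        raise GeometryError("ROI mask shape does not match the frame shape")
    n_roi, n_bg = int(roi_mask.sum()), int(background_mask.sum())
    if n_roi == 0 or n_bg == 0:
        raise GeometryError("zero-area ROI")
    if abs(n_roi - n_bg) > area_tol_px:
        raise GeometryError(
            f"background ROI area {n_bg} px differs from signal ROI {n_roi} px")
    flat = stack.reshape(len(stack), -1)
    raw = flat[:, roi_mask.ravel()].mean(axis=1)
    bg = flat[:, background_mask.ravel()].mean(axis=1)
    return Trace(time_s=np.arange(len(stack)) / fps, corrected=raw - bg,
                 raw=raw, background=bg, roi=roi, channel=channel)


def delta_f_over_f(corrected: np.ndarray) -> np.ndarray:
    """(F_i - F) / F with F the mean of the entire corrected trace."""
    f = np.asarray(corrected, dtype=float)
    fbar = np.nanmean(f)
    if fbar == 0 or np.isnan(fbar):
        raise NormalizationError("whole-trace mean is zero; dF/F undefined")
    return (f - fbar) / fbar


def delta_r_over_r(yfp: np.ndarray, cfp: np.ndarray, time_s: np.ndarray | None = None,
                   normalization_span: tuple[float, float] | None = None) -> RatioTrace:
    """Ratiometric dR/R of a YFP/CFP pair.

    ``normalization_span`` (start, end in seconds) restricts the frames over
    which the reference ratio R is averaged, e.g. the blue-light stimulation
    window; default is the full trace.  Any used frame with CFP <= 0 is an
    error (the ratio is undefined there).
    """
    yfp = np.asarray(yfp, dtype=float)
    cfp = np.asarray(cfp, dtype=float)
    if yfp.shape != cfp.shape:
        raise RatioError("YFP and CFP traces must have equal length")
    bad = np.where(cfp <= 0)[0]
    if bad.size:
        raise RatioError(f"CFP <= 0 at frames {bad[:10].tolist()}")
    t = np.arange(len(yfp), dtype=float) if time_s is None else \
        np.asarray(time_s, dtype=float)
    ratio = yfp / cfp
    if normalization_span is None:
        ref = ratio
    else:
        t0, t1 = normalization_span
        m = (t >= t0) & (t <= t1)
        if not m.any():
            raise RatioError("normalization span contains no frames")
        ref = ratio[m]
    rbar = ref.mean()
    if rbar == 0:
        raise NormalizationError("reference ratio is zero; dR/R undefined")
    return RatioTrace(time_s=t, ratio=ratio, normalized=(ratio - rbar) / rbar,
                      yfp=yfp, cfp=cfp)


@dataclass
class AlignmentResult:
    aligned: dict[str, Trace]
    shift_s: float
    excluded: list[str] = field(default_factory=list)


def align_to_first_peak(traces: dict[str, Trace], reference: str,
                        min_prominence: float | None = None) -> AlignmentResult:
    """Shift a set of traces so the reference trace's first peak sits at t = 0.

    Peaks are local maxima of the reference's normalized-or-corrected values
    with prominence at least ``min_prominence`` (default 2x the trace SD).
    If no peak is found the whole animal's set is reported excluded rather
    than silently dropped.
    """
    ref = traces[reference]
    y = ref.normalized if ref.normalized is not None else ref.corrected
    prom = 2.0 * np.std(y) if min_prominence is None else min_prominence
    peaks, _ = find_peaks(y, prominence=prom)
    if peaks.size == 0:
        return AlignmentResult(aligned={}, shift_s=np.nan,
                               excluded=sorted(traces))
    t_peak = ref.time_s[peaks[0]]
    aligned = {}
    for name, tr in traces.items():
        aligned[name] = Trace(
            time_s=tr.time_s - t_peak, corrected=tr.corrected, raw=tr.raw,
            background=tr.background, normalized=tr.normalized,
            roi=tr.roi, channel=tr.channel)
    return AlignmentResult(aligned=aligned, shift_s=-float(t_peak))
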