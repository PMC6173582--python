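"""Tracking of neuron cell bodies in fluorescence movies of moving worms.

Spots are detected per frame by Otsu binarization of the marker channel and
connected-component centroids, and linked across frames by nearest-neighbour
assignment to the previous position within a gate radius.  Activity is read
out on the (translation-aligned) activity channel as the mean over a circular
ROI centred on the tracked centroid minus the mean over a surrounding
donut-shaped background annulus, which cancels any uniform background offset.
The bending angle at the vulva is the interior angle AS6-vulva-AS7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .errors import AmbiguityError, GeometryError
from .synthetic import interior_angle_deg

__all__ = [
    "SpotTrack",
    "VulvaAngleSeries",
    "track_neurons",
    "vulva_angle",
    "estimate_channel_offset",
]


@dataclass
class SpotTrack:
    label: str
    centroids: np.ndarray     # (T, 2) (row, col); NaN where missing
    corrected: np.ndarray     # (T,) donut-corrected intensity; NaN where missing
    missing: np.ndarray       # (T,) bool


@dataclass
class VulvaAngleSeries:
    time_s: np.ndarray
    angle_deg: np.ndarray     # interior angle at the vulva, (0, 180]
    distance_px: np.ndarray   # AS6-AS7 distance


def _detect_spots(frame: np.ndarray, min_area_px: int = 4) -> np.ndarray:
    """Intensity-weighted centroids of thresholded components, (k, 2)."""
    vals = np.unique(frame)
    if vals.size < 2:
        return np.empty((0, 2))
    thr = threshold_otsu(frame)
    labels = cc_label(frame > thr, connectivity=2)
    cents = [p.centroid_weighted for p in
             regionprops(labels, intensity_image=frame) if p.area >= min_area_px]
    return np.array(cents) if cents else np.empty((0, 2))


def _donut_intensity(frame: np.ndarray, row: float, col: float,
                     roi_radius: float, bg_width: float) -> float:
    H, W = frame.shape
    outer = roi_radius + bg_width
    r0, r1 = int(max(row - outer - 1, 0)), int(min(row + outer + 2, H))
    c0, c1 = int(max(col - outer - 1, 0)), int(min(col + outer + 2, W))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - row, cc - col)
    patch = frame[r0:r1, c0:c1]
    roi = d <= roi_radius
    annulus = (d > roi_radius) & (d <= outer)
    if not roi.any() or not annulus.any():
        raise GeometryError("ROI or annulus empty (spot too close to the border)")
    return float(patch[roi].mean() - patch[annulus].mean())


def track_neurons(activity_stack: np.ndarray, marker_stack: np.ndarray,
                  initial_positions: dict[str, tuple[float, float]],
                  channel_offset: tuple[float, float] = (0.0, 0.0),
                  roi_radius: float = 18.0, bg_width: float = 5.0,
                  gate_px: float = 20.0,
                  gap_tolerance: int = 5) -> dict[str, SpotTrack]:
    """Track labelled spots through the marker channel and read out activity.

    ``initial_positions`` seeds the identities (e.g. AS6/vulva/AS7) near frame
    0.  A frame with no candidate within ``gate_px`` of a spot's last known
    position is flagged missing (the track resumes when the spot reappears);
    two candidates inside the gate raise :class:`AmbiguityError` with the
    frame index.  ``channel_offset`` (dr, dc) maps marker coordinates onto the
    activity channel before the donut read-out.
    """
    if len(activity_stack) != len(marker_stack):
        raise GeometryError("activity and marker stacks differ in length")
    T = len(marker_stack)
    labels = list(initial_positions)
    last = {lab: np.asarray(initial_positions[lab], dtype=float)
            for lab in labels}
    misses = {lab: 0 for lab in labels}
    dr, dc = channel_offset

    tracks = {lab: SpotTrack(label=lab,
                             centroids=np.full((T, 2), np.nan),
                             corrected=np.full(T, np.nan),
                             missing=np.ones(T, dtype=bool))
              for lab in labels}

    for i in range(T):
        cands = _detect_spots(marker_stack[i])
        taken: dict[int, str] = {}
        for lab in labels:
            if cands.size == 0:
                misses[lab] += 1
                continue
            d = np.linalg.norm(cands - last[lab], axis=1)
            in_gate = np.where(d <= gate_px)[0]
            if in_gate.size == 0:
                misses[lab] += 1
                continue
            if in_gate.size > 1:
                raise AmbiguityError(
                    f"frame {i}: {in_gate.size} spots within {gate_px} px gate "
                    f"of '{lab}'")
            j = int(in_gate[0])
            if j in taken:
                raise AmbiguityError(
                    f"frame {i}: spot claimed by both '{taken[j]}' and '{lab}'")
            taken[j] = lab
            pos = cands[j]
            last[lab] = pos
            misses[lab] = 0
            tr = tracks[lab]
            tr.centroids[i] = pos
            tr.corrected[i] = _donut_intensity(
                activity_stack[i], pos[0] + dr, pos[1] + dc,
                roi_radius, bg_width)
            tr.missing[i] = False
    return tracks


def vulva_angle(as6: SpotTrack, vulva: SpotTrack, as7: SpotTrack,
                fps: float) -> VulvaAngleSeries:
    """Interior angle at the vulva between AS6 and AS7, plus AS6-AS7 distance.

    Frames where any of the three spots is missing — or where points coincide
    so the angle is undefined — are NaN.
    """
    T = len(vulva.centroids)
    angle = np.full(T, np.nan)
    dist = np.full(T, np.nan)
    for i in range(T):
        if as6.missing[i] or vulva.missing[i] or as7.missing[i]:
            continue
        try:
            angle[i] = interior_angle_deg(as6.centroids[i], vulva.centroids[i],
                                          as7.centroids[i])
        except Exception:
            continue
        dist[i] = np.linalg.norm(as6.centroids[i] - as7.centroids[i])
    return VulvaAngleSeries(time_s=np.arange(T) / fps, angle_deg=angle,
                            distance_px=dist)


def estimate_channel_offset(activity_frame: np.ndarray,
                            marker_frame: np.ndarray) -> tuple[float, float]:
    """Translational offset (dr, dc) from marker to activity, via phase correlation."""
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(
        activity_frame.astype(float), marker_frame.astype(float),
        upsample_factor=10)
    return float(shift[0]), float(shift[1])
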