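"""Posture metrics from oriented midline sequences.

Metrics follow the conventions of worm-tracker behavioural analysis:

* **2-point angles** — the 99 segment-orientation angles theta of a 100-point
  spine, minus their frame mean ("normalized", which removes the global body
  orientation); stacked over time they form the bending kymograph.
* **3-point angles** — thirteen points at equal arc-length fractions define
  eleven bend angles (180 deg minus the interior angle at each middle point),
  signed dorsal-positive using a per-video ``vulva_side`` declaration.
* **dorso-ventral ratio** — mean dorsal bend over |mean ventral bend| of one
  angle trace (the 2nd of the 11 angles in the tracker analysis).
* **differential bending** — frame-to-frame |change| of each smoothed angle
  trace, averaged within dark/illuminated epochs; the light-minus-dark
  difference summarizes how much a manipulation freezes part of the body.
* **eigenworms** — principal components of the normalized tangent-angle
  library; projections give a low-dimensional posture readout.

Angles are stored in radians internally and reported in degrees.  Invalid
frames propagate as NaN rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ProtocolError, RankError, UndefinedRatioError
from .segmentation import Midline, moving_average

__all__ = [
    "EigenwormBasis",
    "DifferentialBending",
    "two_point_kymograph",
    "three_point_angles",
    "three_point_series",
    "dorsoventral_ratio",
    "differential_bending",
    "fit_eigenworms",
    "project_eigenworms",
    "body_metrics",
]

_SIDE_SIGN = {"dorsal_up": 1.0, "ventral_up": -1.0, "unknown": 1.0}


def _side_sign(vulva_side: str) -> float:
    try:
        return _SIDE_SIGN[vulva_side]
    except KeyError:
        raise ValueError(f"vulva_side must be one of {sorted(_SIDE_SIGN)}") from None


def two_point_kymograph(midlines: list[Midline],
                        vulva_side: str = "unknown") -> np.ndarray:
    """Frames x 99 normalized 2-point angles (radians), dorsal positive.

    Per frame the tangent angles minus their frame mean; the subtraction makes
    a straight worm all zeros regardless of its global orientation.  With
    ``vulva_side='unknown'`` the sign convention is arbitrary (but fixed).
    """
    sign = _side_sign(vulva_side)
    n_seg = next((len(m.theta) for m in midlines if m.valid), 99)
    kymo = np.full((len(midlines), n_seg), np.nan)
    for i, m in enumerate(midlines):
        if m.valid:
            theta = np.unwrap(m.theta)
            kymo[i] = sign * (theta - theta.mean())
    return kymo


def _resample_points(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, cum, points[:, 0])
    out[:, 1] = np.interp(targets, cum, points[:, 1])
    return out


def three_point_angles(midline: Midline,
                       vulva_side: str = "unknown") -> np.ndarray:
    """Eleven signed 3-point bend angles (degrees, dorsal positive).

    Thirteen points are sampled at equal arc-length fractions 0, 1/12, ..., 1
    of the spine; angle i is 180 deg minus the interior angle at point i+1,
    with the sign of the turn direction (cross product) times the declared
    vulva side.
    """
    if not midline.valid:
        return np.full(11, np.nan)
    sign = _side_sign(vulva_side)
    pts = _resample_points(midline.points, 13)
    a = np.diff(pts, axis=0)          # 12 segment vectors
    u, w = a[:-1], a[1:]
    dot = (u * w).sum(axis=1)
    cross = u[:, 1] * w[:, 0] - u[:, 0] * w[:, 1]   # z of (x=col, y=row) cross
    norm = np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1)
    with np.errstate(invalid="ignore"):
        bend = np.degrees(np.arccos(np.clip(dot / norm, -1.0, 1.0)))
    return sign * np.sign(cross) * bend


def three_point_series(midlines: list[Midline],
                       vulva_side: str = "unknown") -> np.ndarray:
    """Frames x 11 signed angle matrix; invalid frames are NaN rows."""
    return np.array([three_point_angles(m, vulva_side) for m in midlines])


def dorsoventral_ratio(angle_trace: np.ndarray) -> float:
    """mean(dorsal bends) / |mean(ventral bends)| of a signed angle trace."""
    x = np.asarray(angle_trace, dtype=float)
    x = x[~np.isnan(x)]
    pos, neg = x[x > 0], x[x < 0]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedRatioError(
            "ratio needs at least one dorsal and one ventral sample")
    return float(pos.mean() / abs(neg.mean()))


@dataclass
class DifferentialBending:
    per_angle_dark: np.ndarray    # (11,) mean |delta| per frame, degrees
    per_angle_light: np.ndarray
    delta_delta: np.ndarray       # light - dark, per angle
    anterior: float               # mean of angles 1-5
    posterior: float              # mean of angles 6-11


def differential_bending(angle_series: np.ndarray, fps: float,
                         protocol: dict[str, tuple[float, float]],
                         smooth_window: int = 15) -> DifferentialBending:
    """Frame-to-frame |change| of each smoothed 3-point angle, dark vs light.

    Each of the 11 angle traces is smoothed with a centred ``smooth_window``
    frame running average; the absolute difference between consecutive frames
    is averaged within the 'dark' and 'light' protocol epochs per angle, and
    the light-minus-dark differences are summarized for the anterior (angles
    1-5) and posterior (angles 6-11) body.
    """
    series = np.asarray(angle_series, dtype=float)
    T = series.shape[0]
    duration = T / fps
    for name in ("dark", "light"):
        if name not in protocol:
            raise ProtocolError(f"protocol must define a '{name}' epoch")
        t0, t1 = protocol[name]
        if not (0 <= t0 < t1 <= duration + 1e-9):
            raise ProtocolError(
                f"epoch '{name}' ({t0}, {t1}) outside the {duration:.2f} s recording")

    smoothed = np.column_stack(
        [moving_average(series[:, j], smooth_window) for j in range(series.shape[1])])
    delta = np.abs(np.diff(smoothed, axis=0))          # (T-1, 11)
    t_mid = (np.arange(T - 1) + 0.5) / fps

    def epoch_mean(name):
        t0, t1 = protocol[name]
        m = (t_mid >= t0) & (t_mid < t1)
        with np.errstate(invalid="ignore"):
            return np.nanmean(delta[m], axis=0)

    dark = epoch_mean("dark")
    light = epoch_mean("light")
    dd = light - dark
    return DifferentialBending(
        per_angle_dark=dark, per_angle_light=light, delta_delta=dd,
        anterior=float(np.nanmean(dd[:5])), posterior=float(np.nanmean(dd[5:])),
    )


@dataclass
class EigenwormBasis:
    mean: np.ndarray              # (99,) mean normalized posture
    components: np.ndarray        # (k, 99) orthonormal rows
    explained_variance: np.ndarray  # (k,) fractions of total variance


def fit_eigenworms(library: np.ndarray, k: int = 4) -> EigenwormBasis:
    """Principal components of a (frames x 99) normalized tangent-angle library."""
    lib = np.asarray(library, dtype=float)
    lib = lib[~np.isnan(lib).any(axis=1)]
    if lib.shape[0] < k:
        raise RankError(f"library has {lib.shape[0]} frames < k={k}")
    mean = lib.mean(axis=0)
    centred = lib - mean
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise RankError(f"k={k} exceeds library rank {rank}")
    var = s ** 2
    return EigenwormBasis(mean=mean, components=vt[:k],
                          explained_variance=var[:k] / var.sum())


def project_eigenworms(theta_frame: np.ndarray, basis: EigenwormBasis) -> np.ndarray:
    """Coefficients of a normalized posture frame in the eigenworm basis."""
    return (np.asarray(theta_frame, dtype=float) - basis.mean) @ basis.components.T


def body_metrics(midlines: list[Midline], mm_per_px: float,
                 fps: float) -> pd.DataFrame:
    """Per-frame body length (mm) and midline centroid (mm)."""
    rows = []
    for i, m in enumerate(midlines):
        if m.valid:
            c = m.points.mean(axis=0) * mm_per_px     # (row, col) -> mm
            rows.append((i / fps, m.arc_length_px * mm_per_px, c[1], c[0]))
        else:
            rows.append((i / fps, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["time_s", "length_mm",
                                       "centroid_x_mm", "centroid_y_mm"])
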