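"""Worm segmentation and midline extraction.

Each grayscale frame is binarized with Otsu's global threshold, components
touching the image border are discarded, the largest remaining component is
taken as the worm, and the mask is cleaned (thicken, remove spur pixels,
majority vote, fill holes — in that order).  The cleaned mask is thinned to a
1-px skeleton, the longest endpoint-to-endpoint geodesic path is taken as the
spine and resampled to an ordered vector of 100 body points with tangent
angles theta from head to tail.  Frames that cannot be analyzed (no worm,
unusually small skeleton, unresolved branching) are flagged invalid and
propagate as missing data, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .errors import EmptySeriesError, NoWormError, ThresholdError

__all__ = [
    "WormMask",
    "Midline",
    "segment_worm",
    "midline_from_mask",
    "orient_and_smooth",
    "segment_video",
    "moving_average",
]


@dataclass
class WormMask:
    mask: np.ndarray          # boolean, frame-sized, single connected component
    area_px: int
    touches_border: bool      # always False for a valid mask
    threshold: float          # chosen Otsu threshold (foreground > threshold)


@dataclass
class Midline:
    """Ordered spine of a single frame; index 0 = head once oriented."""

    points: np.ndarray        # (n, 2) float (row, col), or empty when invalid
    theta: np.ndarray         # (n-1,) tangent angle of successive segments
    arc_length_px: float
    valid: bool = True
    invalid_reason: str | None = None   # no_worm | skeleton_too_small | branching_unresolved

    @classmethod
    def invalid_frame(cls, reason: str) -> "Midline":
        return cls(points=np.empty((0, 2)), theta=np.empty(0),
                   arc_length_px=np.nan, valid=False, invalid_reason=reason)


# ---------------------------------------------------------------------------
# morphological cleanup (MATLAB bwmorph-style operators, fixed small ops)

_SQUARE3 = np.ones((3, 3), dtype=bool)


def _thicken(mask: np.ndarray) -> np.ndarray:
    """One constrained thickening iteration: dilate unless components merge."""
    grown = ndimage.binary_dilation(mask, structure=_SQUARE3)
    if cc_label(grown, connectivity=2).max() == cc_label(mask, connectivity=2).max():
        return grown
    return mask


def _remove_spurs(mask: np.ndarray, iterations: int = 5) -> np.ndarray:
    out = mask.copy()
    for _ in range(iterations):
        nb = ndimage.convolve(out.astype(np.uint8), _SQUARE3.astype(np.uint8),
                              mode="constant") - out
        endpoints = out & (nb == 1)
        if not endpoints.any():
            break
        out &= ~endpoints
    return out


def _majority(mask: np.ndarray) -> np.ndarray:
    counts = ndimage.convolve(mask.astype(np.uint8), _SQUARE3.astype(np.uint8),
                              mode="constant")
    return counts >= 5


def segment_worm(frame: np.ndarray, invert: bool = False,
                 min_area_px: int = 5) -> WormMask:
    """Otsu-threshold a frame and return the cleaned single-worm mask.

    Components containing border pixels are ignored; among the remainder the
    largest-area component is kept, then cleaned (thicken, remove spurs,
    majority, fill holes).  ``invert=True`` selects a dark worm on a bright
    background.
    """
    frame = np.asarray(frame)
    if np.unique(frame).size < 2:
        raise ThresholdError("constant image has no Otsu threshold")
    thr = float(threshold_otsu(frame))
    fg = (frame <= thr) if invert else (frame > thr)

    labels = cc_label(fg, connectivity=2)
    border = np.zeros_like(fg)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_ids = np.unique(labels[border & fg])
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    areas[border_ids] = 0
    if areas.max() < min_area_px:
        raise NoWormError("no non-border foreground component")
    worm = labels == int(areas.argmax())

    worm = _thicken(worm)
    worm = _remove_spurs(worm)
    worm = _majority(worm)
    worm = ndimage.binary_fill_holes(worm)
    return WormMask(mask=worm, area_px=int(worm.sum()), touches_border=False,
                    threshold=thr)


# ---------------------------------------------------------------------------
# skeleton -> ordered midline

_NBR = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(coords: np.ndarray):
    """8-connected pixel graph with Euclidean edge weights."""
    index = {tuple(p): i for i, p in enumerate(coords)}
    rows, cols, wts = [], [], []
    for i, (r, c) in enumerate(coords):
        for dr, dc in _NBR:
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
                wts.append(np.hypot(dr, dc))
    n = len(coords)
    return csr_matrix((wts, (rows, cols)), shape=(n, n))


def _extend_to_boundary(path: np.ndarray, mask: np.ndarray,
                        tangent_pts: int = 6, step: float = 0.5,
                        max_steps: int = 60) -> np.ndarray:
    """Prolong both path ends along their local tangent until leaving the mask.

    Thinning erodes the skeleton away from the head/tail tips by roughly the
    local half-width; walking the end tangent to the mask boundary restores
    the full arc length.
    """
    H, W = mask.shape

    def inside(p):
        r, c = int(round(p[0])), int(round(p[1]))
        return 0 <= r < H and 0 <= c < W and mask[r, c]

    out = [path]
    for sign in (0, -1):
        end = path[-1] if sign == -1 else path[0]
        k = min(tangent_pts, len(path) - 1)
        ref = path[-1 - k] if sign == -1 else path[k]
        tangent = end - ref
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent /= norm
        p = end.copy()
        last_inside = None
        for _ in range(max_steps):
            p = p + step * tangent
            if not inside(p):
                break
            last_inside = p.copy()
        if last_inside is not None:
            if sign == -1:
                out = out + [last_inside[None, :]]
            else:
                out = [last_inside[None, :]] + out
    return np.concatenate(out, axis=0)


def _trim_ends(path: np.ndarray, trim_px: float) -> np.ndarray:
    """Drop ``trim_px`` of arc length from each end of the path.

    Thinning leaves short hooks where the skeleton meets blunt mask ends; the
    trimmed stretch is regrown along the (clean) local tangent by
    :func:`_extend_to_boundary`.
    """
    if trim_px <= 0 or len(path) < 4:
        return path
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 4 * trim_px:
        return path
    keep = (cum >= trim_px) & (cum <= cum[-1] - trim_px)
    return path[keep] if keep.sum() >= 4 else path


def _smooth_polyline(path: np.ndarray, window: int = 5) -> np.ndarray:
    """Light centred smoothing of the pixel path to suppress 8-connected zigzag."""
    if len(path) < window:
        return path
    out = path.copy()
    half = window // 2
    for i in range(len(path)):
        lo, hi = max(0, i - half), min(len(path), i + half + 1)
        out[i] = path[lo:hi].mean(axis=0)
    return out


def _resample_polyline(path: np.ndarray, n_points: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n_points)
    out = np.empty((n_points, 2))
    out[:, 0] = np.interp(targets, cum, path[:, 0])
    out[:, 1] = np.interp(targets, cum, path[:, 1])
    return out


def midline_from_mask(mask: WormMask | np.ndarray, n_points: int = 100,
                      min_skeleton_px: int = 20,
                      prune_px: float = 10.0,
                      end_trim_px: float = 5.0) -> Midline:
    """Thin the mask and return the ordered n-point spine with tangent angles.

    The spine is the longest endpoint-to-endpoint geodesic path through the
    1-px skeleton, resampled to equal arc-length spacing; side branches up to
    ``prune_px`` geodesic length are tolerated.  Returns an invalid Midline
    (reason ``skeleton_too_small`` or ``branching_unresolved``) instead of a
    silent guess on degenerate shapes.
    """
    m = mask.mask if isinstance(mask, WormMask) else np.asarray(mask, bool)
    skel = skeletonize(m)
    coords = np.argwhere(skel)
    if len(coords) < min_skeleton_px:
        return Midline.invalid_frame("skeleton_too_small")

    graph = _skeleton_graph(coords)
    nb_counts = np.asarray((graph > 0).sum(axis=1)).ravel()
    endpoints = np.where(nb_counts == 1)[0]
    if len(endpoints) < 2:
        return Midline.invalid_frame("branching_unresolved")

    dist, pred = dijkstra(graph, indices=endpoints, return_predecessors=True)
    finite = np.where(np.isinf(dist), -1.0, dist)
    k, j = np.unravel_index(np.argmax(finite[:, endpoints]),
                            (len(endpoints), len(endpoints)))
    src, dst = endpoints[k], endpoints[j]
    if finite[k, endpoints[j]] <= 0:
        return Midline.invalid_frame("branching_unresolved")

    path_idx = [dst]
    while path_idx[-1] != src:
        path_idx.append(pred[k, path_idx[-1]])
    path_idx = path_idx[::-1]

    on_path = np.zeros(len(coords), dtype=bool)
    on_path[path_idx] = True
    off = [e for e in endpoints if not on_path[e]]
    if off:
        d_off = dijkstra(graph, indices=off)
        branch_len = d_off[:, on_path].min(axis=1)
        if (branch_len > prune_px).any():
            return Midline.invalid_frame("branching_unresolved")

    path = coords[path_idx].astype(float)
    path = _trim_ends(path, end_trim_px)
    path = _smooth_polyline(path)
    path = _extend_to_boundary(path, m)
    pts = _resample_polyline(path, n_points)
    d = np.diff(pts, axis=0)
    theta = np.arctan2(d[:, 0], d[:, 1])   # atan2(d_row, d_col) == atan2(dy, dx)
    arc = float(np.linalg.norm(d, axis=1).sum())
    return Midline(points=pts, theta=theta, arc_length_px=arc)


# ---------------------------------------------------------------------------
# orientation and smoothing


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, window truncated at the ends."""
    x = np.asarray(x, dtype=float)
    half = window // 2
    out = np.empty_like(x)
    n = len(x)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + window - half)
        w = x[lo:hi]
        w = w[~np.isnan(w)]
        out[i] = w.mean() if w.size else np.nan
    return out


def _flip(m: Midline) -> Midline:
    pts = m.points[::-1].copy()
    d = np.diff(pts, axis=0)
    theta = np.arctan2(d[:, 0], d[:, 1])
    return replace(m, points=pts, theta=theta)


def orient_and_smooth(midlines: list[Midline], fps: float,
                      head_hint: str | tuple[float, float] | None = None,
                      smooth_window: int = 15) -> list[Midline]:
    """Head-first orientation plus along-the-body theta smoothing.

    The first valid frame is oriented by ``head_hint`` ('left'/'right', an
    approximate (row, col) head point) or, if absent, by which end leads the
    net centroid motion over the first second.  Every later frame minimizes
    the summed point-to-point distance to the previous oriented frame.  Theta
    is then smoothed along the 100-point body axis with a centred moving
    average (default window 15, truncated at the ends).  Invalid frames are
    passed through untouched.
    """
    valid_idx = [i for i, m in enumerate(midlines) if m.valid]
    if not valid_idx:
        raise EmptySeriesError("no valid midline in the sequence")

    out = list(midlines)
    first = valid_idx[0]
    m0 = out[first]
    if head_hint == "left":
        do_flip = m0.points[0, 1] > m0.points[-1, 1]
    elif head_hint == "right":
        do_flip = m0.points[0, 1] < m0.points[-1, 1]
    elif head_hint is not None:
        hint = np.asarray(head_hint, dtype=float)
        do_flip = (np.linalg.norm(m0.points[0] - hint)
                   > np.linalg.norm(m0.points[-1] - hint))
    else:
        horizon = [i for i in valid_idx if i <= first + fps]
        if len(horizon) >= 2:
            c_start = out[horizon[0]].points.mean(axis=0)
            c_end = out[horizon[-1]].points.mean(axis=0)
            motion = c_end - c_start
        else:
            motion = np.zeros(2)
        if np.linalg.norm(motion) == 0:
            do_flip = False
        else:
            c = m0.points.mean(axis=0)
            do_flip = np.dot(m0.points[0] - c, motion) < np.dot(
                m0.points[-1] - c, motion)
    if do_flip:
        out[first] = _flip(m0)

    prev = out[first]
    for i in valid_idx[1:]:
        m = out[i]
        keep = np.linalg.norm(m.points - prev.points, axis=1).sum()
        flipped = np.linalg.norm(m.points[::-1] - prev.points, axis=1).sum()
        if flipped < keep:
            m = _flip(m)
            out[i] = m
        prev = m

    for i in valid_idx:
        out[i] = replace(out[i], theta=moving_average(out[i].theta, smooth_window))
    return out


def segment_video(frames: np.ndarray, invert: bool = False,
                  head_hint=None, fps: float = 25.0,
                  smooth_window: int = 15, n_points: int = 100) -> list[Midline]:
    """Full per-frame pipeline: segment, skeletonize, orient, smooth.

    Frames failing segmentation become invalid midlines (missing data) rather
    than raising, so long recordings survive isolated bad frames.
    """
    midlines: list[Midline] = []
    for frame in frames:
        try:
            mask = segment_worm(frame, invert=invert)
        except (NoWormError, ThresholdError):
            midlines.append(Midline.invalid_frame("no_worm"))
            continue
        midlines.append(midline_from_mask(mask, n_points=n_points))
    return orient_and_smooth(midlines, fps=fps, head_hint=head_hint,
                             smooth_window=smooth_window)
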