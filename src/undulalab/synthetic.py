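"""Synthetic worm locomotion, video and fluorescence-movie generators.

Every downstream stage of the pipeline (segmentation, posture, track QC,
fluorescence extraction, neuron tracking, correlation) is exercised against
movies produced here, for which the exact midline, traces and timing
parameters are known.  The locomotion model is a single-harmonic traveling
bending wave on the tangent angle::

    theta(s, t) = A(t) * sin(2*pi*s/lambda - 2*pi*f*t) + B(t) * (s - 1/2)

with ``s`` the arc-length fraction along the body, ``A`` the peak bending
amplitude (rad), ``lambda`` the wavelength in body lengths, ``f`` the wave
frequency (Hz; freely crawling worms undulate at roughly 0.5 Hz) and ``B`` a
dorsal curvature bias: the extra head-to-tail tangent rotation, distributed
uniformly along the body, that makes the worm circle toward its dorsal side
(a constant added to theta itself would merely rotate the worm rigidly).
The midline is reconstructed by integrating unit tangents from the head, so
the ground-truth arc length is exact by construction.  Perturbation epochs rescale A, B, the crawl speed and the body
length multiplicatively, emulating the phenomenology of optogenetic
de-/hyperpolarization (deeper bends, dorsal bias, slowing, contraction)
without any biomechanical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, RenderError

__all__ = [
    "PerturbationEpoch",
    "LocomotionParams",
    "GroundTruth",
    "RenderParams",
    "WormVideo",
    "MuscleMovie",
    "NeuronMovie",
    "generate_locomotion",
    "render_worm_video",
    "generate_muscle_movie",
    "generate_neuron_movie",
]


@dataclass(frozen=True)
class PerturbationEpoch:
    """Multiplicative perturbation of the locomotion model on [t_start, t_end).

    Multipliers of 1.0 leave the corresponding parameter unchanged.
    """

    t_start: float
    t_end: float
    amplitude: float = 1.0  # multiplies A
    bias: float = 1.0       # multiplies B
    speed: float = 1.0      # multiplies v
    length: float = 1.0     # multiplies body length


@dataclass(frozen=True)
class LocomotionParams:
    duration_s: float = 20.0
    fps: float = 25.0
    body_length_mm: float = 1.0
    wave_amplitude_rad: float = 0.3
    wavelength_fraction: float = 0.9
    wave_freq_hz: float = 0.5
    dorsal_bias_rad: float = 0.0
    speed_mm_s: float = 0.1
    freq_jitter: float = 0.0   # fractional SD of smooth frequency modulation
    perturbation_epochs: tuple[PerturbationEpoch, ...] = ()
    n_points: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        if self.fps <= 0:
            raise ParameterError("fps must be > 0")
        if self.body_length_mm <= 0:
            raise ParameterError("body_length_mm must be > 0")
        if self.n_points < 3:
            raise ParameterError("n_points must be >= 3")
        epochs = sorted(self.perturbation_epochs, key=lambda e: e.t_start)
        for i, ep in enumerate(epochs):
            if not (0 <= ep.t_start < ep.t_end <= self.duration_s):
                raise ParameterError(
                    f"epoch {i} ({ep.t_start}, {ep.t_end}) outside [0, {self.duration_s}]"
                )
            if i and ep.t_start < epochs[i - 1].t_end:
                raise ParameterError(f"epoch {i} overlaps epoch {i - 1}")


@dataclass
class GroundTruth:
    """Exact per-frame state of a simulated worm.

    midline_mm has shape (T, n_points, 2) with columns (x, y) in mm, index 0 =
    head; theta has shape (T, n_points - 1): tangent angle of each inter-point
    segment.  state is 'forward' where the instantaneous speed is >= 0,
    'reverse' otherwise.
    """

    time_s: np.ndarray
    midline_mm: np.ndarray
    theta: np.ndarray
    centroid_mm: np.ndarray
    arc_length_mm: np.ndarray
    state: np.ndarray
    params: LocomotionParams

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


def _epoch_multipliers(params: LocomotionParams, t: np.ndarray):
    amp = np.ones_like(t)
    bias = np.ones_like(t)
    speed = np.ones_like(t)
    length = np.ones_like(t)
    for ep in params.perturbation_epochs:
        m = (t >= ep.t_start) & (t < ep.t_end)
        amp[m] *= ep.amplitude
        bias[m] *= ep.bias
        speed[m] *= ep.speed
        length[m] *= ep.length
    return amp, bias, speed, length


def generate_locomotion(params: LocomotionParams) -> GroundTruth:
    """Closed-form traveling-wave locomotion, deterministic given params.

    The worm's mean body axis lies along x; the head (point 0) is on the low-x
    side and the centroid advances toward -x at speed v, so the head leads net
    motion during forward crawling.
    """
    params.validate()
    n = params.n_points
    T = int(round(params.duration_s * params.fps))
    t = np.arange(T) / params.fps
    amp_m, bias_m, speed_m, len_m = _epoch_multipliers(params, t)
    A = params.wave_amplitude_rad * amp_m
    B = params.dorsal_bias_rad * bias_m
    v = params.speed_mm_s * speed_m
    L = params.body_length_mm * len_m

    # temporal phase: exactly 2*pi*f*t, or its integral when the instantaneous
    # frequency is smoothly modulated (real undulation is quasi-periodic; the
    # jitter breaks long-range periodicity so correlogram side lobes decay)
    if params.freq_jitter > 0:
        rng = np.random.default_rng(params.seed)
        z = rng.standard_normal(T)
        win = max(int(params.fps / max(params.wave_freq_hz, 1e-6)), 1)
        kernel = np.ones(win) / win
        z = np.convolve(z, kernel, mode="same")
        sd = z.std()
        if sd > 0:
            z /= sd
        f_inst = params.wave_freq_hz * np.clip(1 + params.freq_jitter * z, 0.1, None)
        tphase = 2 * np.pi * np.concatenate([[0.0], np.cumsum(f_inst[:-1])]) / params.fps
    else:
        tphase = 2 * np.pi * params.wave_freq_hz * t

    # tangent angle evaluated at segment midpoints, one per inter-point segment
    s_mid = (np.arange(n - 1) + 0.5) / (n - 1)
    phase = 2 * np.pi * s_mid[None, :] / params.wavelength_fraction \
        - tphase[:, None]
    theta = A[:, None] * np.sin(phase) + B[:, None] * (s_mid - 0.5)[None, :]

    seg = (L / (n - 1))[:, None]
    dx = seg * np.cos(theta)
    dy = seg * np.sin(theta)
    pts = np.zeros((T, n, 2))
    pts[:, 1:, 0] = np.cumsum(dx, axis=1)
    pts[:, 1:, 1] = np.cumsum(dy, axis=1)

    # recentre each frame on its own centroid, then advance the centroid at -v
    pts -= pts.mean(axis=1, keepdims=True)
    disp = np.concatenate([[0.0], np.cumsum(v[:-1]) / params.fps])
    centroid = np.zeros((T, 2))
    centroid[:, 0] = -disp
    pts += centroid[:, None, :]

    state = np.where(v >= 0, "forward", "reverse")
    return GroundTruth(
        time_s=t,
        midline_mm=pts,
        theta=theta,
        centroid_mm=centroid,
        arc_length_mm=L,
        state=state,
        params=params,
    )


# ---------------------------------------------------------------------------
# video rendering


@dataclass(frozen=True)
class RenderParams:
    image_shape: tuple[int, int] = (320, 720)
    mm_per_px: float = 0.005
    peak_width_mm: float = 0.08   # full body width at the widest point
    width_exponent: float = 0.5   # sin^p taper toward head and tail
    foreground: float = 200.0
    background: float = 20.0
    noise_sd: float = 0.0
    invert: bool = False          # True -> dark worm on bright background
    clutter_blob: bool = False    # extra blob touching the image border
    clutter_radius_px: int = 18
    dtype: str = "uint8"
    seed: int = 0


@dataclass
class WormVideo:
    """Grayscale frame stack with acquisition metadata."""

    frames: np.ndarray            # (T, H, W)
    fps: float
    mm_per_px: float
    origin_px: np.ndarray         # (row, col) of mm-origin, for truth round-trips
    protocol: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def mm_to_px(self, xy_mm: np.ndarray) -> np.ndarray:
        """Map (x, y) mm coordinates to (row, col) pixel coordinates."""
        xy = np.asarray(xy_mm, dtype=float)
        rc = np.empty_like(xy)
        rc[..., 0] = xy[..., 1] / self.mm_per_px + self.origin_px[0]
        rc[..., 1] = xy[..., 0] / self.mm_per_px + self.origin_px[1]
        return rc


def _width_profile_px(render: RenderParams, n: int) -> np.ndarray:
    s = np.arange(n) / (n - 1)
    radius_mm = 0.5 * render.peak_width_mm * np.sin(np.pi * s) ** render.width_exponent
    return radius_mm / render.mm_per_px


def render_worm_video(truth: GroundTruth, render: RenderParams | None = None,
                      protocol: dict[str, tuple[float, float]] | None = None) -> WormVideo:
    """Render the ground-truth midline as a filled worm silhouette per frame.

    Each frame is the union of disks centred on the midline points with radii
    from a smooth sin^p width profile tapering to ~0 at head and tail, plus
    seeded Gaussian noise.  Raises :class:`RenderError` naming the first
    offending frame if the worm does not fit inside the image.
    """
    from skimage.draw import disk as draw_disk

    render = render or RenderParams()
    H, W = render.image_shape
    n = truth.midline_mm.shape[1]
    radii = _width_profile_px(render, n)

    # place the overall trajectory in the image centre
    all_pts = truth.midline_mm.reshape(-1, 2)
    mid_mm = 0.5 * (all_pts.min(axis=0) + all_pts.max(axis=0))
    origin = np.array([H / 2 - mid_mm[1] / render.mm_per_px,
                       W / 2 - mid_mm[0] / render.mm_per_px])
    video = WormVideo(frames=np.empty(0), fps=truth.params.fps,
                      mm_per_px=render.mm_per_px, origin_px=origin,
                      protocol=protocol or {})

    rc = video.mm_to_px(truth.midline_mm)  # (T, n, 2)
    max_r = radii.max()
    bad = np.where(
        (rc[..., 0].min(axis=1) < max_r) | (rc[..., 0].max(axis=1) > H - 1 - max_r)
        | (rc[..., 1].min(axis=1) < max_r) | (rc[..., 1].max(axis=1) > W - 1 - max_r)
    )[0]
    if bad.size:
        raise RenderError(f"worm leaves the frame first at frame {bad[0]}")

    rng = np.random.default_rng(render.seed)
    lo, hi = (0, 255) if render.dtype == "uint8" else (0, 65535)
    fg, bg = render.foreground, render.background
    if render.invert:
        fg, bg = bg, fg
    frames = np.empty((truth.n_frames, H, W), dtype=render.dtype)
    for i in range(truth.n_frames):
        img = np.full((H, W), bg, dtype=float)
        mask = np.zeros((H, W), dtype=bool)
        for j in range(n):
            if radii[j] < 0.5:
                continue
            rr, cc = draw_disk((rc[i, j, 0], rc[i, j, 1]), radii[j], shape=(H, W))
            mask[rr, cc] = True
        img[mask] = fg
        if render.clutter_blob:
            rr, cc = draw_disk((0, 0), render.clutter_radius_px, shape=(H, W))
            img[rr, cc] = fg
        if render.noise_sd > 0:
            img += rng.normal(0.0, render.noise_sd, size=img.shape)
        frames[i] = np.clip(img, lo, hi)
    video.frames = frames
    return video


# ---------------------------------------------------------------------------
# muscle fluorescence movie


@dataclass
class MuscleMovie:
    """Dual-band muscle movie: dorsal ROIs in the top band, ventral in the bottom.

    roi_masks maps labels like 'dorsal_0' / 'ventral_0' to boolean masks;
    background_masks maps the same labels to equal-area dark regions.  truth
    maps labels to the exact noise-free intensity traces.
    """

    frames: np.ndarray
    fps: float
    roi_masks: dict[str, np.ndarray]
    background_masks: dict[str, np.ndarray]
    truth: dict[str, np.ndarray]
    time_s: np.ndarray


def generate_muscle_movie(n_rois_per_side: int = 4, duration_s: float = 20.0,
                          fps: float = 20.0, freq_hz: float = 0.5,
                          antiphase: bool = True,
                          photostim_epoch: tuple[float, float, float, float] | None = None,
                          base: float = 100.0, amp: float = 50.0,
                          noise_sd: float = 0.0, rectify: bool = False,
                          seed: int = 0) -> MuscleMovie:
    """Antiphase dorso-ventral muscle activity with optional photostimulation.

    Dorsal ROI intensity is ``base + amp * w(2*pi*f*t)`` and ventral the same
    with phase pi when ``antiphase``; ``w`` is a sinusoid by default or its
    half-wave rectification with ``rectify=True``.  ``photostim_epoch`` is
    ``(t_start, t_end, dorsal_step, ventral_step)`` added during the epoch.
    The exact per-ROI traces are returned alongside the rendered stack.
    """
    if n_rois_per_side < 1:
        raise ParameterError("n_rois_per_side must be >= 1")
    T = int(round(duration_s * fps))
    t = np.arange(T) / fps
    if photostim_epoch is not None:
        t0, t1 = photostim_epoch[0], photostim_epoch[1]
        if not (0 <= t0 < t1 <= duration_s):
            raise ParameterError(
                f"photostim epoch ({t0}, {t1}) outside [0, {duration_s}]")

    def wave(phase_offset: float) -> np.ndarray:
        w = np.sin(2 * np.pi * freq_hz * t + phase_offset)
        return np.maximum(0.0, w) if rectify else w

    dorsal = base + amp * wave(0.0)
    ventral = base + amp * wave(np.pi if antiphase else 0.0)
    if photostim_epoch is not None:
        t0, t1, dstep, vstep = photostim_epoch
        m = (t >= t0) & (t < t1)
        dorsal = dorsal + dstep * m
        ventral = ventral + vstep * m

    side = 10      # ROI square edge, px
    gap = 4
    H = 6 * side
    W = n_rois_per_side * (side + gap) + gap
    bg_level = 10.0
    rng = np.random.default_rng(seed)

    roi_masks: dict[str, np.ndarray] = {}
    bg_masks: dict[str, np.ndarray] = {}
    truth: dict[str, np.ndarray] = {}
    frames = np.full((T, H, W), bg_level)
    rows = {"dorsal": slice(gap, gap + side),
            "ventral": slice(H - gap - side, H - gap)}
    bg_row = slice(H // 2 - side // 2, H // 2 + side // 2)
    for k in range(n_rois_per_side):
        c = slice(gap + k * (side + gap), gap + k * (side + gap) + side)
        for name, trace in (("dorsal", dorsal), ("ventral", ventral)):
            label = f"{name}_{k}"
            m = np.zeros((H, W), dtype=bool)
            m[rows[name], c] = True
            roi_masks[label] = m
            b = np.zeros((H, W), dtype=bool)
            b[bg_row, c] = True
            bg_masks[label] = b
            truth[label] = trace.copy()
            frames[:, rows[name], c] = bg_level + trace[:, None, None]
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return MuscleMovie(frames=frames, fps=fps, roi_masks=roi_masks,
                       background_masks=bg_masks, truth=truth, time_s=t)


# ---------------------------------------------------------------------------
# dual-neuron tracking movie


@dataclass
class NeuronMovie:
    """Two-channel movie of neuron spots riding a moving midline.

    The marker channel carries three constant-brightness spots (AS6, vulva,
    AS7); the activity channel carries AS6/AS7 spots whose brightness follows
    the true vulva bending angle advanced by a configurable lead.  Truth fields
    hold the exact spot positions (px), activity traces and vulva angle.
    """

    activity: np.ndarray            # (T, H, W)
    marker: np.ndarray              # (T, H, W)
    fps: float
    time_s: np.ndarray
    positions_px: dict[str, np.ndarray]    # label -> (T, 2) (row, col)
    activity_truth: dict[str, np.ndarray]  # label -> (T,)
    vulva_angle_true_deg: np.ndarray
    initial_positions: dict[str, tuple[float, float]]
    channel_offset: tuple[float, float]
    state: np.ndarray


def _point_at_fraction(midline: np.ndarray, frac: float) -> np.ndarray:
    """Interpolate the point at an arc-length fraction of a (n, 2) midline."""
    seg = np.linalg.norm(np.diff(midline, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = frac * cum[-1]
    return np.array([np.interp(target, cum, midline[:, 0]),
                     np.interp(target, cum, midline[:, 1])])


def interior_angle_deg(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    """Interior angle at `vertex` between the rays to p1 and p2, degrees."""
    u = np.asarray(p1, float) - np.asarray(vertex, float)
    w = np.asarray(p2, float) - np.asarray(vertex, float)
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        raise ParameterError("coincident points give no angle")
    c = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _draw_gaussian(img: np.ndarray, row: float, col: float, amp: float,
                   sigma: float) -> None:
    H, W = img.shape
    r0 = max(int(row - 4 * sigma), 0)
    r1 = min(int(row + 4 * sigma) + 1, H)
    c0 = max(int(col - 4 * sigma), 0)
    c1 = min(int(col + 4 * sigma) + 1, W)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amp * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma ** 2))


def generate_neuron_movie(truth: GroundTruth, as6_s: float = 0.3,
                          vulva_s: float = 0.5, as7_s: float = 0.7,
                          activity_lead_s: float = 2.0,
                          activity_lead_as7_s: float = 0.0,
                          image_shape: tuple[int, int] = (192, 192),
                          mm_per_px: float = 0.005,
                          spot_sigma_px: float = 3.0,
                          marker_amp: float = 2000.0,
                          activity_base: float = 500.0,
                          activity_amp: float = 1500.0,
                          channel_offset: tuple[float, float] = (0.0, 0.0),
                          noise_sd: float = 0.0, seed: int = 0) -> NeuronMovie:
    """Render AS6/vulva/AS7 spots on the moving midline with known activity lead.

    ``activity_lead_s`` is the time by which AS6 activity leads the true vulva
    bending angle (AS7 analogously).  The activity trace is the normalized
    future vulva angle, so a cross-correlation of extracted activity against
    the measured angle has its peak at exactly the configured lead.
    """
    if not (0 <= as6_s < vulva_s < as7_s <= 1):
        raise ParameterError(
            f"need 0 <= as6_s < vulva_s < as7_s <= 1, got {(as6_s, vulva_s, as7_s)}")
    T = truth.n_frames
    t = truth.time_s
    H, W = image_shape

    pts_mm = {lab: np.array([_point_at_fraction(truth.midline_mm[i], f)
                             for i in range(T)])
              for lab, f in (("AS6", as6_s), ("vulva", vulva_s), ("AS7", as7_s))}
    all_pts = np.concatenate(list(pts_mm.values()))
    mid = 0.5 * (all_pts.min(axis=0) + all_pts.max(axis=0))
    origin = np.array([H / 2 - mid[1] / mm_per_px, W / 2 - mid[0] / mm_per_px])

    def to_px(xy: np.ndarray) -> np.ndarray:
        rc = np.empty_like(xy)
        rc[:, 0] = xy[:, 1] / mm_per_px + origin[0]
        rc[:, 1] = xy[:, 0] / mm_per_px + origin[1]
        return rc

    pos = {lab: to_px(v) for lab, v in pts_mm.items()}
    margin = 4 * spot_sigma_px
    for lab, rc in pos.items():
        if (rc[:, 0].min() < margin or rc[:, 0].max() > H - 1 - margin
                or rc[:, 1].min() < margin or rc[:, 1].max() > W - 1 - margin):
            raise RenderError(f"spot {lab} leaves the frame")

    angle = np.array([interior_angle_deg(pos["AS6"][i], pos["vulva"][i],
                                         pos["AS7"][i]) for i in range(T)])
    ptp = angle.max() - angle.min()
    norm_angle = (angle - angle.min()) / ptp if ptp > 0 else np.zeros(T)

    def activity_for(lead: float) -> np.ndarray:
        # future angle; clamped at the trace end for the final `lead` seconds
        return activity_base + activity_amp * np.interp(t + lead, t, norm_angle)

    act = {"AS6": activity_for(activity_lead_s),
           "AS7": activity_for(activity_lead_as7_s),
           "vulva": np.full(T, activity_base)}

    rng = np.random.default_rng(seed)
    dr, dc = channel_offset
    activity_stack = np.zeros((T, H, W))
    marker_stack = np.zeros((T, H, W))
    for i in range(T):
        for lab in ("AS6", "vulva", "AS7"):
            r, c = pos[lab][i]
            _draw_gaussian(marker_stack[i], r, c, marker_amp, spot_sigma_px)
            _draw_gaussian(activity_stack[i], r + dr, c + dc, act[lab][i],
                           spot_sigma_px)
    if noise_sd > 0:
        activity_stack += noise_sd * rng.standard_normal(
            activity_stack.shape, dtype=np.float32)
        marker_stack += noise_sd * rng.standard_normal(
            marker_stack.shape, dtype=np.float32)

    return NeuronMovie(
        activity=activity_stack, marker=marker_stack, fps=truth.params.fps,
        time_s=t, positions_px=pos, activity_truth=act,
        vulva_angle_true_deg=angle,
        initial_positions={lab: tuple(pos[lab][0]) for lab in pos},
        channel_offset=channel_offset, state=truth.state,
    )
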