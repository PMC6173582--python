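# Methods

`undulalab` re-implements, as a tested pipeline, the video and Ca²⁺-imaging
analysis used to characterize motor-neuron function in crawling *C. elegans*:
worm segmentation and midline extraction, posture metrics and kymographs,
behavioral track quality control, fluorescence trace normalization,
dual-neuron tracking with vulva-angle geometry, and event-wise
cross-correlation of neural activity with body bending. Because no public
recordings accompany the analysis, every stage is validated against a
synthetic-data generator whose ground truth is exact by construction.

## The locomotion model

The generator describes the body by its tangent angle on the arc-length
fraction *s* ∈ [0, 1]:

θ(s, t) = A(t)·sin(2π·s/λ − φ(t)) + B(t)·(s − ½)

* **A** — peak bending amplitude (rad; default 0.3, a moderately deep
  crawl).
* **λ** — wavelength in body lengths (default 0.9: slightly less than one
  full wave on the body, typical of agar crawling).
* **φ(t)** — temporal phase. By default φ = 2π·f·t with f the wave frequency
  (default 0.5 Hz, the free-crawling undulation rate). With `freq_jitter > 0`
  the instantaneous frequency is smoothly modulated (seeded Gaussian noise,
  low-pass filtered over one undulation period, fractional SD = the jitter),
  and φ is its integral. Real undulation is quasi-periodic; the jitter is
  what makes lag estimation from cross-correlograms well-posed (see below).
* **B** — dorsal curvature bias: the extra head-to-tail tangent rotation,
  distributed uniformly along the body. A *constant* added to θ would rotate
  the worm rigidly without bending it; distributing the rotation along *s*
  curves the body to one side and produces circling tracks, the phenomenology
  of dorsally biased motor drive.

The midline is reconstructed by integrating unit tangents from the head, so
the arc length equals the configured body length (default 1 mm) exactly. The
centroid advances along the mean body axis at speed v (default 0.1 mm/s);
v < 0 marks reversal frames. Perturbation epochs rescale A, B, v and the body
length multiplicatively over a time window — a phenomenological stand-in for
optogenetic de-/hyperpolarization (deeper bends, dorsal bias, slowing,
contraction). There is no biomechanics: no muscle forces, no proprioception,
no camera photon model.

Rendering draws filled disks along the midline with a sin^p half-width taper
(p = 0.5, peak width 0.08 mm) at 0.005 mm/px, matching the proportions of an
adult worm (~80 µm wide at 1 mm long). The taper guarantees a single
connected blob whose skeleton runs head to tail.

## Segmentation and midline

Frames are binarized with Otsu's global threshold (scikit-image);
components touching the image border are discarded, the largest remaining
component is the worm, and the mask is cleaned in the order thicken (one
dilation constrained not to merge components), remove spur pixels (5
iterations), majority vote (one pass), fill holes. The cleaned mask is
thinned to a 1-px skeleton; the spine is the longest endpoint-to-endpoint
geodesic path (Dijkstra over the 8-connected pixel graph, Euclidean
weights), tolerating side branches up to 10 px.

Thinning erodes the skeleton away from the tapered head and tail and leaves
small hooks at blunt ends, so the path is trimmed by 5 px of arc at each
end, lightly smoothed (5-point centred average, against 8-connectivity
zigzag), and then re-extended along each end's local tangent to the mask
boundary. The result is resampled to 100 points at equal arc-length spacing;
θ is the atan2 of successive segment vectors. On noise-free synthetic video
this recovers the true midline with < 1 px RMS point error and < 1% arc
error; residual distortion of a few degrees remains on rasterized
constant-curvature shapes (pixel-staircase geodesics).

Frames that cannot be analyzed return an invalid midline with a reason
(`no_worm`, `skeleton_too_small` — skeleton under 20 px, `branching_unresolved`)
and propagate as missing values, never as zeros. Self-intersecting postures
(omega turns) are out of scope and flagged invalid.

Head/tail orientation is automated: the first valid frame uses a hint
(side or approximate head point) or, failing that, the end leading net
centroid motion over the first second; later frames minimize the summed
point-to-point distance to the previous frame. θ is then smoothed **along
the body** with a 15-point centred moving average (window truncated at the
ends). Whether that 15-sample smoothing window is spatial or temporal was an
open choice; we read it as spatial (the kymograph's body axis) and expose the
window, and `differential_bending` separately applies a 15-**frame** temporal
window where frame-to-frame angle changes are the quantity of interest.

## Posture metrics

* **2-point angles / kymograph** — the 99 segment angles θ minus their frame
  mean; the subtraction removes global orientation, so a straight worm maps
  to zero everywhere. Sign is dorsal-positive given a per-video `vulva_side`
  declaration (with `unknown`, the convention is arbitrary but fixed).
* **3-point angles** — 13 points at equal arc fractions 0, 1/12, …, 1 give
  11 angles, each 180° minus the interior angle at the middle point, signed
  by turn direction × vulva side. Computed from dot/cross products so that
  mirroring the midline with the side flag flipped reproduces the angles
  bit-for-bit.
* **Dorso-ventral ratio** — mean of positive samples over |mean of negative
  samples| of one signed angle trace (by convention the 2nd of 11); an error,
  not infinity, when either side has no samples.
* **Differential bending** — each angle trace is smoothed (15 frames), the
  |difference| between consecutive frames is averaged per dark/light epoch,
  and light−dark differences are summarized for anterior (angles 1–5) and
  posterior (6–11) body.
* **Eigenworms** — principal components (SVD) of a mean-centred library of
  normalized θ frames; projections are inner products with the components.
  No published basis is bundled; the basis is fitted to a provided library
  (synthetic or user data) or loaded from CSV.

Angles are stored in radians and reported in degrees.

## Track quality control

Speed is the per-frame centroid displacement × fps, smoothed with a 15-frame
centred average (the cap below is applied to the smoothed trace;
configurable). Frames are discarded when speed exceeds 1.25 mm/s or body
length deviates more than 25% from the baseline (mean over valid frames of
the first 5 s). A recording is excluded when **more than** 15% of frames are
discarded — exactly 15% does not exclude. Filtering is idempotent. Window
statistics report mean ± SEM (n−1 denominator) of valid samples per named
epoch; empty windows are missing, not zero.

## Fluorescence traces

ROI traces are per-frame means over a signal ROI minus an equal-area
background ROI; equal area (within 1 px) makes the subtraction an unbiased
offset estimate. ΔF/F = (F_i − F̄)/F̄ with F̄ the mean of the entire corrected
trace — hence mean(ΔF/F) = 0 and invariance to positive rescaling, but *not*
to additive offsets, which is why background subtraction must come first.
Ratiometric (cameleon) traces use R_i = YFP/CFP and ΔR/R = (R_i − R̄)/R̄; R̄
defaults to the full trace with a stimulation-window option (both spans are
in use in the field; neither is guessed as the single intent). Multi-ROI sets
are aligned by shifting time so the first peak of a reference trace (local
maxima with prominence ≥ 2× trace SD by default) sits at t = 0; animals
without a reference peak are reported excluded, not dropped silently.

## Neuron tracking

Spots are detected per frame by Otsu binarization of the marker channel and
intensity-weighted component centroids (sub-pixel, < 0.5 px RMS on clean
spots). Identities (AS6 / vulva / AS7) are seeded by initial positions and
linked frame-to-frame by nearest neighbour within a 20 px gate; two
candidates in the gate raise an ambiguity error naming the frame, and frames
with no candidate are flagged missing while the track waits to resume.
Activity is read on the activity channel — aligned by a translational
channel offset, supplied or estimated by phase correlation — as the mean
over an 18 px-radius circular ROI centred on the tracked centroid minus the
mean over the surrounding 5 px-wide annulus; the donut cancels any uniform
background offset exactly. The vulva bending angle is the interior angle
AS6–vulva–AS7 (0–180°], with the AS6–AS7 distance as a companion readout.

## Event-wise cross-correlation

Traces are smoothed with a 10-frame centred average. Bending events are the
segments of the (smoothed) angle trace between consecutive local minima
(prominence default 10% of peak-to-peak; events under 1 s dropped and
counted). The lag grid is ±100 steps of a 10 samples/s analysis rate — a
±10 s span; traces at other rates are linearly resampled to 10 Hz first (the
imaging rate, 20 fps, and the lag-grid rate differ; resampling reconciles
them). Per event and lag, the value is the Pearson correlation of the
lag-shifted overlapping samples, so every value lies in [−1, 1]; positive
lag means the first signal leads the second. A lag leaving fewer than 10
overlapping samples (1 s) in an event is missing for that event — a Pearson
over two or three points is ±1 by construction and would otherwise dominate
the aggregate. Correlograms aggregate as mean ± SEM over events.

The signed peak is the largest-|value| mean correlation (sign preserved),
searched within a 5 s window centred on the peak lag of a control mean
correlogram when one is given. Exact magnitude ties — a noise-free periodic
signal ties the peak and the half-period trough at ±1 — are broken by
preferring the positive value, then the smallest |lag|. Reversal epochs are
maximal runs of reverse frames lasting ≥ 10 s.

## The dual-neuron scenario and what it shows

The end-to-end recovery scenario mimics imaging a crawling worm under a
tracking stage: net speed 0 (the stage holds the vulva region in view), wave
frequency 0.1 Hz with 25% frequency jitter, 80 s at 20 fps. Two geometric
facts shape these defaults. First, the unsigned vulva angle dips once per
half undulation — the interior angle cannot distinguish dorsal from ventral
bends — so bending events last half an undulation period; 0.1 Hz yields
~5 s events, matching slowed under-coverslip crawling, and leaves enough
overlap inside an event to measure a 2 s lag. Second, for a strictly
periodic wave a 2 s lead is indistinguishable from a lead of 2 s minus the
period; the frequency jitter decorrelates the signal away from zero offset,
so the event-averaged correlogram has a unique peak at the true lead.
AS6 activity is the normalized future vulva angle (advanced by the
configured lead, clamped over the final seconds of the trace); AS7 activity
coincides with the angle. The full pipeline — spot tracking, donut read-out,
angle geometry, event segmentation, correlation — recovers the configured
2.0 s AS6 lead and the 0 s AS7 lag to within one lag step (0.1 s) across
seeds.

Passing these tests shows the *measurement chain* is correct on data whose
generative model is known. It does not certify performance on real
recordings, which add posture-dependent fluorescence artifacts, focus drift,
omega turns, occlusions and photobleaching that the generator deliberately
omits.

## Numerical choices and limitations

* Problem sizes: synthetic videos of 20–1600 frames at 0.005 mm/px and
  192²–720·320 px frames; chosen as the smallest sizes at which every
  recovery check is measurable with comfortable margins.
* Half-up rounding for whole-number synapse percents (68/144 → 47.22 → 47,
  66/144 → 45.83 → 46); per-source fractions sum to 1 within 1e-12.
* The muscle generator's default waveform is an antiphase sinusoid;
  `rectify=True` half-wave rectifies it (a crude Ca²⁺-indicator
  nonlinearity). Rectification caps the achievable dorsal/ventral
  anticorrelation near −0.68, so reciprocity checks use the sinusoidal
  default.
* Degenerate inputs error loudly: constant images (no threshold), filled
  disks (no spine), one-sided bending (undefined ratio), zero-mean traces
  (undefined ΔF/F), CFP ≤ 0 (undefined ratio), coincident spots (undefined
  angle — missing frame).
* MATLAB's exact `bwmorph` operators are not bit-specified cross-platform;
  the thicken/spur/majority implementations here are small fixed operators
  with the iteration counts stated above, all configurable.
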