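"""End-to-end synthetic study scenarios shared by the analysis drivers and tests.

Each scenario wires the generator through the full measurement pipeline with
fixed, documented study conditions, so parameter-recovery results are
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import correlation as corr
from . import fluorescence as fluo
from . import neuron_tracking as ntrack
from . import synthetic as syn

__all__ = ["NeuronCorrelationResult", "neuron_correlation_scenario",
           "muscle_reciprocity_scenario"]


@dataclass
class NeuronCorrelationResult:
    tracks: dict
    vulva_angle: "ntrack.VulvaAngleSeries"
    events: "corr.EventSet"
    as6_vs_angle: "corr.CorrelogramSet"
    as7_vs_angle: "corr.CorrelogramSet"
    as6_vs_as7: "corr.CorrelogramSet"
    movie: "syn.NeuronMovie"


def neuron_correlation_scenario(seed: int = 0, activity_lead_s: float = 2.0,
                                duration_s: float = 80.0,
                                noise_sd: float = 2.0) -> NeuronCorrelationResult:
    """Dual-neuron tracking scenario: AS6 activity leads the vulva angle.

    A stage-tracked worm (net speed 0: the imaging stage keeps the vulva
    region in view) undulates at 0.1 Hz with 25% smooth frequency jitter, so
    one bending event — the segment between two minima of the unsigned vulva
    angle — lasts about 5 s, matching slowed under-coverslip crawling.  AS6
    activity is the vulva angle advanced by ``activity_lead_s``; AS7 activity
    coincides with the angle.  The full pipeline (spot tracking, donut
    read-out, vulva-angle geometry, event segmentation, event-wise
    cross-correlation) then re-measures the configured lead.
    """
    params = syn.LocomotionParams(
        duration_s=duration_s, fps=20.0, wave_freq_hz=0.1,
        wave_amplitude_rad=0.35, speed_mm_s=0.0, freq_jitter=0.25, seed=seed)
    truth = syn.generate_locomotion(params)
    movie = syn.generate_neuron_movie(
        truth, activity_lead_s=activity_lead_s, activity_lead_as7_s=0.0,
        noise_sd=noise_sd, seed=seed + 1)
    tracks = ntrack.track_neurons(movie.activity, movie.marker,
                                  movie.initial_positions)
    angle = ntrack.vulva_angle(tracks["AS6"], tracks["vulva"], tracks["AS7"],
                               fps=params.fps)
    as6 = corr.preprocess(tracks["AS6"].corrected)
    as7 = corr.preprocess(tracks["AS7"].corrected)
    ang = corr.preprocess(angle.angle_deg)
    events = corr.segment_events(ang, fps=params.fps)
    return NeuronCorrelationResult(
        tracks=tracks, vulva_angle=angle, events=events,
        as6_vs_angle=corr.xcorr_events(events, as6, ang),
        as7_vs_angle=corr.xcorr_events(events, as7, ang),
        as6_vs_as7=corr.xcorr_events(events, as6, as7),
        movie=movie)


def muscle_reciprocity_scenario(seed: int = 0, noise_sd: float = 1.0):
    """Antiphase dorso-ventral muscle movie pushed through trace extraction.

    Returns ``(movie, dff)`` where dff maps each ROI label to its
    background-corrected Delta F/F trace.
    """
    movie = syn.generate_muscle_movie(noise_sd=noise_sd, seed=seed)
    dff = {}
    for lab in movie.roi_masks:
        tr = fluo.extract_roi_trace(movie.frames, movie.roi_masks[lab],
                                    movie.background_masks[lab],
                                    fps=movie.fps, roi=lab)
        dff[lab] = fluo.delta_f_over_f(tr.corrected)
    return movie, dff
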