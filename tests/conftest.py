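"""Shared fixtures: small synthetic movies with exact ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from undulalab import synthetic as syn
from undulalab.segmentation import Midline


def truth_to_midlines(truth: syn.GroundTruth) -> list[Midline]:
    """Wrap ground-truth midlines as Midline objects (mm units, (row, col)=(y, x))."""
    out = []
    for i in range(truth.n_frames):
        pts = truth.midline_mm[i][:, ::-1].copy()   # (x, y) -> (row=y, col=x)
        d = np.diff(pts, axis=0)
        out.append(Midline(points=pts, theta=np.arctan2(d[:, 0], d[:, 1]),
                           arc_length_px=float(np.linalg.norm(d, axis=1).sum())))
    return out


@pytest.fixture(scope="session")
def crawl_truth() -> syn.GroundTruth:
    """4 s of forward crawling at 0.5 Hz undulation."""
    params = syn.LocomotionParams(duration_s=4.0, fps=5.0, wave_freq_hz=0.5,
                                  wave_amplitude_rad=0.3, speed_mm_s=0.1)
    return syn.generate_locomotion(params)


@pytest.fixture(scope="session")
def crawl_video(crawl_truth) -> syn.WormVideo:
    """Noise-free rendering of crawl_truth (20 frames)."""
    return syn.render_worm_video(crawl_truth)


@pytest.fixture(scope="session")
def crawl_midlines(crawl_video):
    from undulalab.segmentation import segment_video

    return segment_video(crawl_video.frames, fps=crawl_video.fps)


@pytest.fixture(scope="session")
def neuron_scenario():
    """Full dual-neuron tracking + correlation scenario (AS6 leads by 2 s)."""
    from undulalab.scenarios import neuron_correlation_scenario

    return neuron_correlation_scenario(seed=7)
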