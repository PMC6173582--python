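"""Generator contracts: closed-form wave, determinism, epochs, movie truth."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from undulalab import fluorescence as fluo
from undulalab import synthetic as syn
from undulalab.errors import ParameterError, RenderError


def params(**kw):
    base = dict(duration_s=4.0, fps=10.0, wave_freq_hz=0.5,
                wave_amplitude_rad=0.3, speed_mm_s=0.1)
    base.update(kw)
    return syn.LocomotionParams(**base)


class TestGenerateLocomotion:
    def test_zero_amplitude_gives_straight_worm(self):
        truth = syn.generate_locomotion(params(wave_amplitude_rad=0.0,
                                               dorsal_bias_rad=0.0))
        assert np.allclose(truth.theta, 0.0)
        # collinear: all y equal within each frame
        assert np.allclose(truth.midline_mm[..., 1],
                           truth.midline_mm[:, :1, 1])

    def test_wave_period_matches_frequency(self):
        # 0.5 Hz undulation -> theta at a fixed body point repeats every 2.0 s
        truth = syn.generate_locomotion(params(duration_s=20.0, fps=25.0))
        trace = truth.theta[:, 50]
        peaks, _ = find_peaks(trace)
        spacing = np.diff(peaks) / 25.0
        assert np.allclose(spacing, 2.0, atol=1 / 25.0)

    def test_constant_bias_gives_one_signed_bends(self):
        from undulalab.posture import three_point_series
        from .conftest import truth_to_midlines

        truth = syn.generate_locomotion(params(dorsal_bias_rad=0.2,
                                               duration_s=8.0))
        angles = three_point_series(truth_to_midlines(truth))
        means = np.nanmean(angles, axis=0)
        assert (np.sign(means) == np.sign(means[0])).all()

    def test_arc_length_follows_epoch_multiplier(self):
        ep = syn.PerturbationEpoch(t_start=1.0, t_end=2.0, length=0.9)
        truth = syn.generate_locomotion(params(perturbation_epochs=(ep,)))
        inside = (truth.time_s >= 1.0) & (truth.time_s < 2.0)
        assert np.allclose(truth.arc_length_mm[inside], 0.9)
        assert np.allclose(truth.arc_length_mm[~inside], 1.0)
        # midline arc length matches the declared value to < 0.1%
        seg = np.linalg.norm(np.diff(truth.midline_mm, axis=1), axis=2).sum(axis=1)
        assert np.allclose(seg, truth.arc_length_mm, rtol=1e-3)

    def test_reversal_state_follows_speed_sign(self):
        ep = syn.PerturbationEpoch(t_start=1.0, t_end=2.0, speed=-1.0)
        truth = syn.generate_locomotion(params(perturbation_epochs=(ep,)))
        inside = (truth.time_s >= 1.0) & (truth.time_s < 2.0)
        assert (truth.state[inside] == "reverse").all()
        assert (truth.state[~inside] == "forward").all()

    @pytest.mark.parametrize("epochs", [
        ((0.5, 0.2),),              # start >= end
        ((-1.0, 1.0),),             # before recording
        ((1.0, 9.0),),              # past the end
        ((0.0, 2.0), (1.5, 3.0)),   # overlapping
    ])
    def test_invalid_epochs_rejected(self, epochs):
        eps = tuple(syn.PerturbationEpoch(a, b) for a, b in epochs)
        with pytest.raises(ParameterError, match="epoch"):
            syn.generate_locomotion(params(perturbation_epochs=eps))

    def test_deterministic_given_seed(self):
        p = params(freq_jitter=0.3, seed=42)
        a = syn.generate_locomotion(p)
        b = syn.generate_locomotion(p)
        assert np.array_equal(a.midline_mm, b.midline_mm)
        assert np.array_equal(a.theta, b.theta)


class TestRenderWormVideo:
    def test_deterministic_given_seed(self, crawl_truth):
        rp = syn.RenderParams(noise_sd=3.0, seed=9)
        a = syn.render_worm_video(crawl_truth, rp)
        b = syn.render_worm_video(crawl_truth, rp)
        assert np.array_equal(a.frames, b.frames)

    def test_out_of_frame_names_first_bad_frame(self, crawl_truth):
        rp = syn.RenderParams(image_shape=(40, 40))
        with pytest.raises(RenderError, match="frame 0"):
            syn.render_worm_video(crawl_truth, rp)

    def test_flat_contrast_yields_no_worm_downstream(self, crawl_truth):
        from undulalab.errors import NoWormError, ThresholdError
        from undulalab.segmentation import segment_worm

        rp = syn.RenderParams(foreground=20.0, background=20.0)
        video = syn.render_worm_video(crawl_truth, rp)
        with pytest.raises((NoWormError, ThresholdError)):
            segment_worm(video.frames[0])

    def test_clutter_blob_does_not_displace_worm_mask(self, crawl_truth):
        from undulalab.segmentation import segment_worm

        video = syn.render_worm_video(
            crawl_truth, syn.RenderParams(clutter_blob=True, clutter_radius_px=40))
        mask = segment_worm(video.frames[0]).mask
        # the selected blob is the worm: its centroid is near the image centre,
        # not the border clutter
        r, c = np.argwhere(mask).mean(axis=0)
        assert r > 60 and c > 60


class TestMuscleMovie:
    def test_antiphase_truth_is_anticorrelated(self):
        movie = syn.generate_muscle_movie(noise_sd=0.0)
        r = np.corrcoef(movie.truth["dorsal_0"], movie.truth["ventral_0"])[0, 1]
        assert r < -0.99

    def test_photostim_steps_have_stated_signs(self):
        movie = syn.generate_muscle_movie(
            noise_sd=0.0, photostim_epoch=(5.0, 10.0, 0.5 * 50, -0.3 * 50))
        m = (movie.time_s >= 5.0) & (movie.time_s < 10.0)
        for lab, sign in (("dorsal_0", 1), ("ventral_0", -1)):
            tr = fluo.extract_roi_trace(
                movie.frames, movie.roi_masks[lab],
                movie.background_masks[lab], fps=movie.fps)
            dff = fluo.delta_f_over_f(tr.corrected)
            assert np.sign(dff[m].mean() - dff[~m].mean()) == sign

    def test_flat_signal_gives_zero_dff(self):
        movie = syn.generate_muscle_movie(amp=0.0, noise_sd=0.0)
        tr = fluo.extract_roi_trace(movie.frames, movie.roi_masks["dorsal_0"],
                                    movie.background_masks["dorsal_0"],
                                    fps=movie.fps)
        assert np.allclose(fluo.delta_f_over_f(tr.corrected), 0.0, atol=1e-9)

    def test_epoch_outside_movie_rejected(self):
        with pytest.raises(ParameterError):
            syn.generate_muscle_movie(photostim_epoch=(15.0, 30.0, 1.0, 1.0))

    def test_rectified_waveform_is_nonnegative_modulation(self):
        movie = syn.generate_muscle_movie(rectify=True, noise_sd=0.0,
                                          base=100.0, amp=50.0)
        assert movie.truth["dorsal_0"].min() >= 100.0 - 1e-9


class TestNeuronMovie:
    def test_fraction_order_enforced(self, crawl_truth):
        with pytest.raises(ParameterError):
            syn.generate_neuron_movie(crawl_truth, as6_s=0.6, vulva_s=0.5,
                                      as7_s=0.7)

    def test_stationary_straight_worm_gives_constant_geometry(self):
        truth = syn.generate_locomotion(params(wave_amplitude_rad=0.0,
                                               speed_mm_s=0.0))
        movie = syn.generate_neuron_movie(truth, noise_sd=0.0)
        for lab in ("AS6", "vulva", "AS7"):
            assert np.ptp(movie.positions_px[lab], axis=0).max() < 1e-9
        assert np.allclose(movie.vulva_angle_true_deg, 180.0)

    def test_activity_is_angle_advanced_by_lead(self):
        truth = syn.generate_locomotion(params(duration_s=20.0, fps=20.0,
                                               speed_mm_s=0.0))
        movie = syn.generate_neuron_movie(truth, activity_lead_s=1.0,
                                          noise_sd=0.0)
        ang = movie.vulva_angle_true_deg
        norm = (ang - ang.min()) / np.ptp(ang)
        lead_frames = 20
        got = movie.activity_truth["AS6"][:-lead_frames]
        expect = 500.0 + 1500.0 * norm[lead_frames:]
        assert np.allclose(got, expect, atol=1e-6)
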