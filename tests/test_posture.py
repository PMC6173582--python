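"""Posture metrics: analytic oracles, symmetry properties, PCA identities."""

import numpy as np
import pytest

from undulalab import posture
from undulalab.errors import ProtocolError, RankError, UndefinedRatioError
from undulalab.segmentation import Midline

from .conftest import truth_to_midlines


def midline_from_points(pts: np.ndarray) -> Midline:
    pts = np.asarray(pts, dtype=float)
    d = np.diff(pts, axis=0)
    return Midline(points=pts, theta=np.arctan2(d[:, 0], d[:, 1]),
                   arc_length_px=float(np.linalg.norm(d, axis=1).sum()))


def straight_midline(angle_rad: float, n: int = 100) -> Midline:
    t = np.linspace(0, 200, n)
    pts = np.column_stack([t * np.sin(angle_rad), t * np.cos(angle_rad)])
    return midline_from_points(pts)


def arc_midline(total_turn: float = np.pi / 2, n: int = 100) -> Midline:
    phi = np.linspace(0, total_turn, n)
    pts = np.column_stack([100 * (1 - np.cos(phi)), 100 * np.sin(phi)])
    return midline_from_points(pts)


def rigid_transform(pts: np.ndarray, angle: float, shift: np.ndarray) -> np.ndarray:
    rot = np.array([[np.cos(angle), -np.sin(angle)],
                    [np.sin(angle), np.cos(angle)]])
    return pts @ rot.T + shift


class TestTwoPointKymograph:
    @pytest.mark.parametrize("angle", [0.0, 0.7, -2.1])
    def test_straight_worm_is_all_zeros(self, angle):
        kymo = posture.two_point_kymograph([straight_midline(angle)])
        assert np.allclose(kymo, 0.0, atol=1e-9)

    def test_quarter_circle_is_linear_and_zero_at_midpoint(self):
        kymo = posture.two_point_kymograph([arc_midline()])[0]
        fit = np.polyfit(np.arange(99), kymo, 1)
        resid = kymo - np.polyval(fit, np.arange(99))
        assert np.abs(resid).max() < 1e-6
        assert abs(kymo[49]) < 0.01

    def test_rows_sum_to_zero(self, crawl_midlines):
        kymo = posture.two_point_kymograph(crawl_midlines)
        assert np.nanmax(np.abs(np.nansum(kymo, axis=1))) < 1e-9

    def test_traveling_wave_stripes_advance_at_wave_speed(self):
        # stripe slope: time lag between body points s1 and s2 is (s2-s1)/(lambda*f)
        from undulalab import synthetic as syn

        p = syn.LocomotionParams(duration_s=20.0, fps=25.0, wave_freq_hz=0.5,
                                 wavelength_fraction=0.9, speed_mm_s=0.0)
        truth = syn.generate_locomotion(p)
        kymo = posture.two_point_kymograph(truth_to_midlines(truth))
        t = truth.time_s
        carrier = np.exp(-2j * np.pi * 0.5 * t)
        phases = np.unwrap(np.angle(kymo.T @ carrier))
        s_mid = (np.arange(99) + 0.5) / 99
        gradient = (phases[-1] - phases[0]) / (s_mid[-1] - s_mid[0])
        # spatial phase gradient 2*pi/lambda => stripes advance head->tail at
        # lambda*f body lengths per second
        assert abs(gradient) == pytest.approx(2 * np.pi / 0.9, rel=0.02)

    def test_unknown_vulva_side_still_produces_kymograph(self):
        kymo = posture.two_point_kymograph([arc_midline()], vulva_side="unknown")
        assert np.isfinite(kymo).all()


class TestThreePointAngles:
    def test_collinear_is_zero(self):
        a = posture.three_point_angles(straight_midline(0.4))
        assert np.allclose(a, 0.0, atol=1e-5)   # arccos noise near 1.0

    def test_right_angle_magnitude(self):
        # 13 sample points forming a single right-angle corner at the middle
        pts = np.concatenate([
            np.column_stack([np.zeros(7), np.linspace(0, 6, 7)]),
            np.column_stack([np.linspace(1, 6, 6), np.full(6, 6.0)])])
        angles = posture.three_point_angles(midline_from_points(pts))
        assert np.isclose(np.abs(angles).max(), 90.0, atol=1e-6)

    def test_mirror_with_side_flip_is_exactly_invariant(self, crawl_midlines):
        for m in crawl_midlines[:5]:
            a = posture.three_point_angles(m, vulva_side="dorsal_up")
            mirrored = midline_from_points(m.points * np.array([-1.0, 1.0]))
            b = posture.three_point_angles(mirrored, vulva_side="ventral_up")
            assert np.array_equal(a, b)

    def test_mirror_without_flip_inverts_all_signs(self, crawl_midlines):
        m = crawl_midlines[0]
        a = posture.three_point_angles(m, vulva_side="dorsal_up")
        mirrored = midline_from_points(m.points * np.array([-1.0, 1.0]))
        b = posture.three_point_angles(mirrored, vulva_side="dorsal_up")
        assert np.array_equal(a, -b)

    def test_rigid_motion_invariance(self, crawl_midlines):
        rng = np.random.default_rng(4)
        m = crawl_midlines[0]
        ref = posture.three_point_angles(m)
        for _ in range(20):
            pts = rigid_transform(m.points, rng.uniform(0, 2 * np.pi),
                                  rng.uniform(-50, 50, 2))
            got = posture.three_point_angles(midline_from_points(pts))
            assert np.allclose(got, ref, atol=np.degrees(1e-6))

    def test_invalid_midline_gives_nan_row(self):
        a = posture.three_point_angles(Midline.invalid_frame("no_worm"))
        assert np.isnan(a).all()


class TestDorsoventralRatio:
    def test_symmetric_bending_is_one(self):
        trace = np.tile([10.0, -10.0], 20)
        assert posture.dorsoventral_ratio(trace) == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        assert posture.dorsoventral_ratio([20, 20, -10, -10]) == pytest.approx(2.0)

    def test_one_sided_trace_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            posture.dorsoventral_ratio([5.0, 10.0, 2.0])


class TestDifferentialBending:
    protocol = {"dark": (0.0, 4.0), "light": (4.0, 8.0)}

    def test_static_posture_is_all_zero(self):
        series = np.tile(np.linspace(-20, 20, 11), (80, 1))
        out = posture.differential_bending(series, fps=10.0, protocol=self.protocol)
        assert np.allclose(out.per_angle_dark, 0) and np.allclose(
            out.per_angle_light, 0)
        assert out.anterior == 0 and out.posterior == 0

    def test_linear_ramp_is_smoothing_invariant(self):
        series = np.tile(np.arange(80.0)[:, None], (1, 11))   # 1 deg/frame
        # epochs away from the trace ends, where the truncated smoothing
        # window leaves the ramp slope exactly 1 deg/frame
        protocol = {"dark": (1.0, 4.0), "light": (4.0, 7.0)}
        out = posture.differential_bending(series, fps=10.0, protocol=protocol)
        assert np.allclose(out.per_angle_dark, 1.0, atol=1e-9)
        assert np.allclose(out.per_angle_light, 1.0, atol=1e-9)
        assert abs(out.anterior) < 1e-9 and abs(out.posterior) < 1e-9

    def test_freeze_during_light_reduces_posterior_movement(self):
        from undulalab import synthetic as syn

        ep = syn.PerturbationEpoch(t_start=4.0, t_end=8.0, amplitude=0.0)
        p = syn.LocomotionParams(duration_s=8.0, fps=20.0, wave_freq_hz=0.5,
                                 speed_mm_s=0.0, perturbation_epochs=(ep,))
        truth = syn.generate_locomotion(p)
        series = posture.three_point_series(truth_to_midlines(truth))
        out = posture.differential_bending(series, fps=20.0, protocol=self.protocol)
        assert out.posterior < 0

    def test_epoch_outside_recording_rejected(self):
        series = np.zeros((40, 11))
        with pytest.raises(ProtocolError):
            posture.differential_bending(
                series, fps=10.0, protocol={"dark": (0, 2), "light": (2, 99)})


class TestEigenworms:
    @staticmethod
    def sinusoid_library(n_frames=200, seed=0):
        rng = np.random.default_rng(seed)
        s = np.arange(99) / 99
        phases = rng.uniform(0, 2 * np.pi, n_frames)
        amps = rng.uniform(0.5, 1.0, n_frames)
        lib = amps[:, None] * np.sin(2 * np.pi * s[None, :] / 0.9
                                     - phases[:, None])
        return lib - lib.mean(axis=1, keepdims=True)

    def test_projecting_a_component_gives_a_unit_vector(self):
        basis = posture.fit_eigenworms(self.sinusoid_library(), k=2)
        for j in range(2):
            coeffs = posture.project_eigenworms(
                basis.mean + basis.components[j], basis)
            expect = np.zeros(2)
            expect[j] = 1.0
            assert np.allclose(coeffs, expect, atol=1e-8)

    def test_full_basis_reconstructs_exactly(self):
        lib = self.sinusoid_library(n_frames=50)
        basis = posture.fit_eigenworms(lib, k=np.linalg.matrix_rank(lib))
        frame = lib[7]
        coeffs = posture.project_eigenworms(frame, basis)
        recon = basis.mean + coeffs @ basis.components
        assert np.allclose(recon, frame, atol=1e-8)

    def test_two_components_explain_sinusoid_postures(self):
        basis = posture.fit_eigenworms(self.sinusoid_library(), k=2)
        # oracle: eigendecomposition of the covariance matrix
        lib = self.sinusoid_library()
        cov = np.cov(lib - lib.mean(axis=0), rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert basis.explained_variance.sum() > 0.95
        assert np.allclose(sorted(basis.explained_variance, reverse=True),
                           (evals[:2] / evals.sum()), rtol=1e-6)

    def test_components_are_orthonormal(self):
        basis = posture.fit_eigenworms(self.sinusoid_library(), k=2)
        gram = basis.components @ basis.components.T
        assert np.allclose(gram, np.eye(2), atol=1e-8)

    def test_k_beyond_rank_rejected(self):
        with pytest.raises(RankError):
            posture.fit_eigenworms(self.sinusoid_library(n_frames=40), k=30)


class TestBodyMetrics:
    def test_rectangle_worm_length(self):
        t = np.linspace(0, 200, 100)
        m = midline_from_points(np.column_stack([np.full(100, 20.0), t]))
        df = posture.body_metrics([m], mm_per_px=0.005, fps=25.0)
        assert df["length_mm"][0] == pytest.approx(1.0, rel=0.02)

    def test_contraction_epoch_shortens_measured_length(self, crawl_truth):
        from undulalab import synthetic as syn

        ep = syn.PerturbationEpoch(t_start=1.0, t_end=2.0, length=0.9)
        p = syn.LocomotionParams(duration_s=4.0, fps=5.0,
                                 perturbation_epochs=(ep,))
        truth = syn.generate_locomotion(p)
        df = posture.body_metrics(truth_to_midlines(truth), mm_per_px=1.0,
                                  fps=5.0)
        inside = (df["time_s"] >= 1.0) & (df["time_s"] < 2.0)
        ratio = df.loc[inside, "length_mm"].mean() / \
            df.loc[~inside, "length_mm"].mean()
        assert ratio == pytest.approx(0.9, abs=0.01)

    def test_single_frame_video_is_fine(self):
        m = straight_midline(0.0)
        df = posture.body_metrics([m], mm_per_px=0.01, fps=25.0)
        assert len(df) == 1 and np.isfinite(df["length_mm"][0])
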