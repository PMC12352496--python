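"""Eye tracking: circle fits, cornea referencing, calibration, gain pipeline."""

import numpy as np
import pytest

from dsgckit import okr, synth
from dsgckit.errors import CalibrationError, InvalidInputError, UnrecoverableTraceError
from dsgckit.okr import EyeTrace, MarkerFrame, PupilFit, StimSpec


def circle_points(center, radius, n=8, likelihood=1.0):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([
        center[0] + radius * np.cos(ang),
        center[1] + radius * np.sin(ang),
        np.full(n, likelihood),
    ])
    return pts


def frame(pupil, reflections=None):
    if reflections is None:
        reflections = np.array([[0.0, 0.0, 1.0], [2.0, 0.0, 1.0], [1.0, 3.0, 1.0]])
    return MarkerFrame(pupil=pupil, reflections=reflections)


class TestPupilCircle:
    def test_eight_exact_points(self):
        fit = okr.fit_pupil_circle(frame(circle_points((5.0, 5.0), 2.0)))
        assert fit.center == pytest.approx((5.0, 5.0))
        assert fit.radius == pytest.approx(2.0)
        assert fit.n_markers_used == 8

    def test_three_points_determine_circle(self):
        pupil = circle_points((5.0, 5.0), 2.0)
        pupil[3:, 2] = 0.1  # only the first three are trusted
        fit = okr.fit_pupil_circle(frame(pupil))
        assert fit.center == pytest.approx((5.0, 5.0))
        assert fit.radius == pytest.approx(2.0)
        assert fit.n_markers_used == 3

    def test_two_markers_carry_forward_previous(self):
        pupil = circle_points((9.0, 9.0), 2.0)
        pupil[2:, 2] = 0.1
        prev = PupilFit(center=(5.0, 5.0), radius=2.0, n_markers_used=8)
        fit = okr.fit_pupil_circle(frame(pupil), previous=prev)
        assert fit.imputed
        assert fit.center == (5.0, 5.0)

    def test_no_prior_and_too_few_markers_unrecoverable(self):
        pupil = circle_points((5.0, 5.0), 2.0, likelihood=0.1)
        with pytest.raises(UnrecoverableTraceError):
            okr.fit_pupil_circle(frame(pupil))

    def test_batch_matches_per_frame(self):
        rng = np.random.default_rng(0)
        frames = []
        for k in range(20):
            pupil = circle_points((5.0 + 0.1 * k, 5.0), 2.0)
            pupil[:, :2] += rng.normal(0, 0.01, (8, 2))
            if k % 7 == 3:
                pupil[:, 2] = 0.1
            frames.append(pupil)
        centers, radii, imputed = okr.track_pupil(np.stack(frames))
        prev = None
        for k, pupil in enumerate(frames):
            fit = okr.fit_pupil_circle(frame(pupil), previous=prev)
            if not fit.imputed:
                prev = fit
            np.testing.assert_allclose(centers[k], fit.center, atol=1e-9)
            assert imputed[k] == fit.imputed

    def test_noisy_center_error_shrinks_with_sigma(self):
        rng = np.random.default_rng(1)
        sigma, r, reps = 0.05, 2.0, 200
        errs = []
        for _ in range(reps):
            pupil = circle_points((5.0, 5.0), r)
            pupil[:, :2] += rng.normal(0, sigma, (8, 2))
            fit = okr.fit_pupil_circle(frame(pupil))
            errs.append(np.hypot(fit.center[0] - 5.0, fit.center[1] - 5.0))
        assert np.mean(errs) < 5 * sigma / np.sqrt(8)


class TestCorneaReference:
    def test_subtracts_reference(self):
        refl = np.array([[[4.0, 4.0, 1.0], [4.0, 4.0, 1.0], [4.0, 4.0, 1.0]]])
        rel, flagged = okr.reference_to_cornea(np.array([[10.0, 10.0]]), refl)
        np.testing.assert_allclose(rel[0], [6.0, 6.0])
        assert not flagged[0]

    def test_centroid_of_high_confidence_reflections(self):
        refl = np.array([[[0.0, 0.0, 1.0], [2.0, 0.0, 1.0], [1.0, 3.0, 1.0]]])
        rel, _ = okr.reference_to_cornea(np.array([[0.0, 0.0]]), refl)
        np.testing.assert_allclose(rel[0], [-1.0, -1.0])

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        centers = rng.uniform(0, 10, (30, 2))
        refl = np.broadcast_to(
            np.array([[0.0, 0.0, 1.0], [2.0, 0.0, 1.0], [1.0, 3.0, 1.0]]), (30, 3, 3)
        ).copy()
        rel1, _ = okr.reference_to_cornea(centers, refl)
        shift = np.array([7.0, -3.0])
        refl2 = refl.copy()
        refl2[:, :, :2] += shift
        rel2, _ = okr.reference_to_cornea(centers + shift, refl2)
        np.testing.assert_allclose(rel1, rel2, atol=1e-12)

    def test_missing_reflections_carry_forward_and_flag(self):
        refl = np.broadcast_to(
            np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]), (3, 3, 3)
        ).copy()
        refl[1, :, 2] = 0.0
        rel, flagged = okr.reference_to_cornea(np.zeros((3, 2)), refl)
        assert flagged.tolist() == [False, True, False]
        np.testing.assert_allclose(rel, -np.ones((3, 2)))


class TestCalibration:
    @pytest.mark.parametrize("dist,expected", [(24.0, 0.5), (12.0, 1.0)])
    def test_scale_from_mean_distance(self, dist, expected):
        a = np.zeros((10, 2))
        b = np.column_stack([np.full(10, dist), np.zeros(10)])
        assert okr.calibrate_scale(a, b) == pytest.approx(expected)

    def test_round_trip_through_generator(self):
        spec = synth.EyeSimSpec(dropout_prob=0.0, position_noise_sd=0.0, duration=5.0)
        a, b, truth = synth.gen_eye_markers(spec, 0, scale_deg_per_px=0.5)
        pa, ra = okr.markers_from_dataframe(a)
        pb, rb = okr.markers_from_dataframe(b)
        ca, _, _ = okr.track_pupil(pa)
        cb, _, _ = okr.track_pupil(pb)
        rel_a, _ = okr.reference_to_cornea(ca, ra)
        rel_b, _ = okr.reference_to_cornea(cb, rb)
        scale = okr.calibrate_scale(rel_a, rel_b)
        assert scale == pytest.approx(0.5, rel=0.01)

    def test_zero_distance_rejected(self):
        with pytest.raises(CalibrationError):
            okr.calibrate_scale(np.zeros((5, 2)), np.zeros((5, 2)))


class TestEyeTrace:
    def test_linear_position_gives_constant_velocity(self):
        n, fps = 200, 100.0
        centers = np.column_stack([0.04 * np.arange(n), np.zeros(n)])  # px
        trace = okr.build_eye_trace(centers, np.zeros(n, bool), 0.5, fps)
        np.testing.assert_allclose(trace.vx[10:-10], 2.0, atol=1e-9)

    def test_constant_position_zero_velocity(self):
        trace = okr.build_eye_trace(np.ones((50, 2)), np.zeros(50, bool), 0.5, 100.0)
        np.testing.assert_allclose(trace.v_total, 0.0, atol=1e-12)

    def test_smoothing_attenuates_impulse_velocity(self):
        n = 100
        pos = np.zeros((n, 2))
        pos[50, 0] = 5.0
        smoothed = okr.build_eye_trace(pos, np.zeros(n, bool), 1.0, 100.0,
                                       gaussian_sigma=2.0)
        unsmoothed = okr.build_eye_trace(pos, np.zeros(n, bool), 1.0, 100.0,
                                         gaussian_sigma=0.0)
        assert smoothed.v_total.max() < unsmoothed.v_total.max()


class TestClassification:
    def _const_velocity_trace(self, v_dps, fps=100.0, n=300):
        pos = np.column_stack([v_dps / fps * np.arange(n), np.zeros(n)])
        return okr.build_eye_trace(pos, np.zeros(n, bool), 1.0, fps)

    @pytest.mark.parametrize("v,label", [(29.0, "slow"), (31.0, "saccade")])
    def test_threshold_sides(self, v, label):
        trace = self._const_velocity_trace(v)
        labels = okr.classify_frames(trace)
        assert all(lbl == label for lbl in labels[10:-10])

    def test_generator_saccades_recovered(self):
        spec = synth.EyeSimSpec(gain_true=0.5, saccade_rate=0.4, duration=20.0,
                                position_noise_sd=0.0, dropout_prob=0.0)
        a, b, truth = synth.gen_eye_markers(spec, 4)
        _, trace = okr.process_presentation(a, b, truth.stim, fps=spec.fps)
        detected = np.asarray(trace.labels, dtype=object) == "saccade"
        # every ground-truth saccade frame is detected within a 1-frame halo
        halo = detected | np.roll(detected, 1) | np.roll(detected, -1)
        assert np.all(halo[truth.saccade_frames])


class TestSlowPursuitAndGain:
    def _trace(self, pos_xy, labels, stim):
        n = pos_xy.shape[0]
        return EyeTrace(
            t=np.arange(n) / 100.0, x_deg=pos_xy[:, 0], y_deg=pos_xy[:, 1],
            vx=np.zeros(n), vy=np.zeros(n), v_total=np.zeros(n),
            labels=np.asarray(labels, dtype=object), scale=1.0, fps=100.0,
            x_raw_deg=pos_xy[:, 0], y_raw_deg=pos_xy[:, 1], stim=stim,
        )

    def test_perfect_tracking_integral(self):
        stim = StimSpec("anterior", velocity=2.0, duration=45.0)
        n = 4500
        pos = np.column_stack([2.0 / 100.0 * np.arange(n), np.zeros(n)])
        trace = self._trace(pos, ["slow"] * n, stim)
        cum, no_slow = okr.cumulative_slow_pursuit(trace)
        assert not no_slow
        assert cum == pytest.approx(90.0, rel=0.01)

    def test_opposite_motion_is_negative(self):
        stim = StimSpec("anterior", velocity=2.0, duration=1.0)
        pos = np.column_stack([-0.02 * np.arange(100), np.zeros(100)])
        cum, _ = okr.cumulative_slow_pursuit(self._trace(pos, ["slow"] * 100, stim))
        assert cum < 0

    def test_orthogonal_motion_projects_to_zero(self):
        stim = StimSpec("anterior", velocity=2.0, duration=1.0)
        pos = np.column_stack([np.zeros(100), 0.02 * np.arange(100)])
        cum, _ = okr.cumulative_slow_pursuit(self._trace(pos, ["slow"] * 100, stim))
        assert cum == pytest.approx(0.0, abs=1e-12)

    def test_no_slow_frames_flagged(self):
        stim = StimSpec("anterior", velocity=2.0, duration=1.0)
        pos = np.zeros((100, 2))
        cum, no_slow = okr.cumulative_slow_pursuit(
            self._trace(pos, ["saccade"] * 100, stim)
        )
        assert cum == 0.0 and no_slow

    @pytest.mark.parametrize("cum,expected", [(90.0, 1.0), (0.0, 0.0), (-45.0, -0.5)])
    def test_gain_ratio_and_sign(self, cum, expected):
        stim = StimSpec("posterior", velocity=2.0, duration=45.0)
        res = okr.okr_gain(cum, stim)
        assert res.gain == pytest.approx(expected)
        assert res.axis == "horizontal"

    def test_zero_stimulus_displacement_rejected(self):
        with pytest.raises(InvalidInputError):
            okr.okr_gain(1.0, StimSpec("superior", velocity=0.0, duration=45.0))

    def test_saccades_barely_perturb_slow_integral(self):
        # same latent pursuit with and without saccades: the slow integral
        # changes only through excluded boundary frames
        base = dict(gain_true=0.6, position_noise_sd=0.0, dropout_prob=0.0,
                    duration=30.0)
        a0, b0, t0 = synth.gen_eye_markers(synth.EyeSimSpec(saccade_rate=0.0, **base), 8)
        a1, b1, t1 = synth.gen_eye_markers(synth.EyeSimSpec(saccade_rate=0.3, **base), 8)
        g0, _ = okr.process_presentation(a0, b0, t0.stim)
        g1, _ = okr.process_presentation(a1, b1, t1.stim)
        # saccade-free recovery exact up to the first-frame difference
        assert abs(g0.gain - 0.6) < 1e-3
        assert abs(g1.gain - 0.6) < 0.05
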