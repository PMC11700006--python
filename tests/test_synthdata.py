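"""Generator fidelity: waveforms, rendering, artifacts, projections."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiotrack import synthdata as sd
from cardiotrack.errors import (DegenerateInputError, InvalidParameterError,
                                OutOfFieldError)
from cardiotrack.params import TrajectoryParams, sequence_preset


class TestTrajectory:
    def test_waveform_peak_to_peak_exact_at_extrema(self):
        """cos^4 cardiac and sine respiratory waveforms hit their stated
        peak-to-peak amplitudes exactly at the analytic extrema."""
        p = TrajectoryParams()
        # cardiac: max at t=0, min at a quarter period of the cos argument
        t_min = 30.0 / p.cardiac_rate_bpm
        card = p.cardiac_waveform(np.array([0.0, t_min]))
        assert abs((card[0] - card[1]) - p.cardiac_p2p_mm) < 1e-9
        assert card.min() >= 0.0  # nonnegative pulse train
        # respiratory: extrema at t = 15/rate and 45/rate
        t_ext = np.array([15.0, 45.0]) / p.resp_rate_bpm
        resp = p.resp_waveform(t_ext)
        assert abs((resp[0] - resp[1]) - p.resp_p2p_mm) < 1e-9

    def test_respiratory_period_is_five_seconds_at_12_bpm(self):
        p = TrajectoryParams()
        t = np.linspace(0.0, 20.0, 333)
        assert np.allclose(p.resp_waveform(t), p.resp_waveform(t + 5.0),
                           atol=1e-9)

    def test_sampled_trace_peak_to_peak(self):
        """With the default 10 ms sampling over 20 s the sampled trace's
        respiratory peak-to-peak reaches the parameter value to within
        the sampling-induced quantization."""
        p = TrajectoryParams(cardiac_p2p_mm=0.0)
        trace = sd.make_trajectory(p)
        assert abs(np.ptp(trace.pos_mm) - p.resp_p2p_mm) < 1e-3

    def test_zero_amplitudes_give_constant_zero_trace(self):
        p = TrajectoryParams(cardiac_p2p_mm=0.0, resp_p2p_mm=0.0)
        trace = sd.make_trajectory(p)
        assert np.all(trace.pos_mm == 0.0)

    @pytest.mark.parametrize("kwargs", [
        {"duration_s": -1.0},
        {"sample_dt_ms": 0.0},
        {"cardiac_rate_bpm": 0.0},
        {"cardiac_p2p_mm": -1.0},
        {"cardiac_shape": "square"},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            TrajectoryParams(**kwargs)

    def test_duration_must_cover_a_respiratory_period(self):
        with pytest.raises(InvalidParameterError):
            sd.make_trajectory(TrajectoryParams(duration_s=3.0))


class TestPhantomCine:
    def test_static_noiseless_scene_renders_identical_frames(self):
        traj = sd.make_trajectory(TrajectoryParams(
            cardiac_p2p_mm=0.0, resp_p2p_mm=0.0, duration_s=6.0))
        seq = sequence_preset("bSSFP", "coronal")
        cine = sd.render_phantom_cine(traj, seq, noise_sd=0.0, n_frames=5)
        for k in range(1, 5):
            assert np.array_equal(cine.frames[k], cine.frames[0])

    def test_rendering_deterministic_given_seed(self):
        traj = sd.make_trajectory(TrajectoryParams(duration_s=6.0))
        seq = sequence_preset("bSSFP", "coronal")
        a = sd.render_phantom_cine(traj, seq, noise_sd=0.05, seed=7, n_frames=4)
        b = sd.render_phantom_cine(traj, seq, noise_sd=0.05, seed=7, n_frames=4)
        assert np.array_equal(a.frames, b.frames)

    def test_disk_centroid_matches_requested_position(self):
        """A disk rendered at +5 mm head-feet has its intensity centroid
        within 0.1 px of the requested position (partial-volume edge is
        symmetric)."""
        from cardiotrack.containers import MotionTrace
        traj = MotionTrace(np.array([0.0, 1000.0]), np.full((2, 1), 5.0),
                           ("HF",), source="phantom_reference")
        seq = sequence_preset("bSSFP", "coronal")
        cine = sd.render_phantom_cine(traj, seq, noise_sd=0.0, n_frames=1)
        frame = cine.frames[0]
        w = np.clip(frame - 0.75, 0.0, None)  # isolates the bright target
        rr, cc = np.mgrid[: frame.shape[0], : frame.shape[1]]
        centroid = np.array([np.sum(w * rr), np.sum(w * cc)]) / np.sum(w)
        expected = cine.mm_to_px(np.array([5.0, 30.0]))
        assert np.all(np.abs(centroid - expected) < 0.1)

    def test_frame_period_comes_from_sequence(self):
        traj = sd.make_trajectory(TrajectoryParams(duration_s=6.0))
        cine = sd.render_phantom_cine(
            traj, sequence_preset("bSSFP", "coronal"), n_frames=3)
        assert cine.dt_ms == 96.0

    def test_out_of_field_error_names_first_offending_frame(self):
        traj = sd.make_trajectory(TrajectoryParams(
            resp_p2p_mm=400.0, duration_s=6.0))
        seq = sequence_preset("bSSFP", "coronal")
        with pytest.raises(OutOfFieldError) as err:
            sd.render_phantom_cine(traj, seq, n_frames=30)
        assert err.value.frame is not None
        assert str(err.value.frame) in str(err.value)


class TestLVCine:
    @staticmethod
    def _flat_resp(duration_s=6.0):
        return sd.make_trajectory(TrajectoryParams(
            cardiac_p2p_mm=0.0, resp_p2p_mm=0.0, duration_s=duration_s))

    def test_zero_motion_gives_constant_landmark_tracks(self):
        seq = sequence_preset("bSSFP", "coronal")
        _, tracks = sd.render_lv_cine(
            self._flat_resp(), lambda t: np.zeros_like(np.asarray(t, float)),
            seq, n_frames=6, contraction_p2p_mm=0.0)
        for lm in tracks:
            assert np.allclose(lm.pos_mm, lm.pos_mm[0])

    def test_contraction_p2p_appears_radially_in_truth(self):
        seq = sequence_preset("bSSFP", "coronal")
        _, tracks = sd.render_lv_cine(
            self._flat_resp(), sd.cos4_phase(70.0), seq, n_frames=30,
            contraction_p2p_mm=10.0)
        for lm in tracks:
            radii = np.sqrt(np.sum(lm.pos_mm**2, axis=1))
            assert abs(np.ptp(radii) - 10.0) < 0.1

    def test_landmarks_sit_on_rendered_endocardial_edge(self):
        """Re-detecting the pool/myocardium edge along each landmark's
        radial ray recovers the stored track within half a pixel."""
        seq = sequence_preset("bSSFP", "coronal")
        cine, tracks = sd.render_lv_cine(
            self._flat_resp(), sd.cos4_phase(70.0), seq, n_frames=10,
            contraction_p2p_mm=8.0, noise_sd=0.0)
        pool, myo = 1.0, 0.5
        half = 0.5 * (pool + myo)
        px = cine.pixel_mm[0]
        for lm in tracks:
            for k in range(cine.n_frames):
                direction = lm.pos_mm[k] / np.linalg.norm(lm.pos_mm[k])
                radii = np.arange(5.0, 35.0, 0.05)
                pts = np.stack([cine.mm_to_px(r * direction) for r in radii])
                from scipy import ndimage
                vals = ndimage.map_coordinates(
                    cine.frames[k], pts.T, order=1, mode="nearest")
                crossing = radii[np.argmax(vals < half)]
                r_truth = np.linalg.norm(lm.pos_mm[k])
                assert abs(crossing - r_truth) < 0.5 * px

    def test_void_artifact_zeroes_pixels_in_every_frame(self):
        seq = sequence_preset("T1-GRE", "coronal")
        art = sd.ArtifactModel(device_center_mm=(0.0, 25.0, 0.0),
                               void_radius_mm=8.0, mode="void",
                               field_amplitude_hz=0.0)
        cine, _ = sd.render_lv_cine(
            self._flat_resp(), sd.cos4_phase(70.0), seq, artifact=art,
            n_frames=5, noise_sd=0.0)
        void = art.void_mask_2d(cine.shape, cine.pixel_mm)
        assert void.any()
        assert np.all(cine.frames[:, void] == 0.0)


class TestArtifacts:
    def test_banding_null_at_half_cycle_offset(self):
        # at df = 1/(2 TR) the per-TR phase accrual is pi: signal null
        tr_ms = 2.8
        df = 1000.0 / (2.0 * tr_ms)
        assert sd.bssfp_attenuation(np.array([df]), tr_ms)[0] == pytest.approx(0.0, abs=1e-12)
        assert sd.bssfp_attenuation(np.array([0.0]), tr_ms)[0] == 1.0

    def test_zero_amplitude_leaves_bssfp_unchanged_outside_void(self):
        seq = sequence_preset("bSSFP", "coronal")
        traj = sd.make_trajectory(TrajectoryParams(
            cardiac_p2p_mm=0.0, resp_p2p_mm=0.0, duration_s=6.0))
        cine = sd.render_phantom_cine(traj, seq, noise_sd=0.0, n_frames=2)
        art = sd.ArtifactModel(device_center_mm=(0.0, -40.0, 0.0),
                               field_amplitude_hz=0.0, void_radius_mm=5.0)
        out = sd.apply_cied_artifact(cine, seq, art)
        void = art.void_mask_2d(cine.shape, cine.pixel_mm)
        assert np.array_equal(out.frames[:, ~void], cine.frames[:, ~void])
        assert np.all(out.frames[:, void] == 0.0)

    def test_gre_has_no_zero_band_outside_void(self):
        """The spoiled-GRE dephasing attenuation is strictly positive, so
        a device that creates a bSSFP null band leaves no null outside
        the void in the gradient-echo image."""
        seq_gre = sequence_preset("T1-GRE", "coronal")
        art = sd.ArtifactModel(device_center_mm=(0.0, -40.0, 0.0),
                               field_amplitude_hz=600.0,
                               reference_distance_mm=12.0, void_radius_mm=5.0)
        offres = art.offres_map_2d((70, 70), (3.2, 3.2))
        bssfp_att = sd.bssfp_attenuation(offres, 2.8)
        gre_att = sd.gre_dephasing_attenuation(offres, seq_gre.te_ms, (3.2, 3.2))
        void = art.void_mask_2d((70, 70), (3.2, 3.2))
        assert np.any(bssfp_att[~void] < 0.1)  # deep banding present for bSSFP
        assert np.all(gre_att[~void] > 0.0)

    def test_offres_magnitude_decays_along_rays_beyond_void(self):
        art = sd.ArtifactModel(field_amplitude_hz=200.0,
                               reference_distance_mm=10.0, void_radius_mm=4.0)
        for direction in ([1, 0, 0], [0, 1, 0], [1, 1, 1], [2, 1, 3]):
            d = np.asarray(direction, float)
            d /= np.linalg.norm(d)
            radii = np.linspace(4.5, 40.0, 100)
            vals = np.abs(art.offres_hz(radii[:, None] * d))
            assert np.all(np.diff(vals) <= 1e-12)


class TestFieldmapAndProjections:
    def test_zero_amplitude_gives_zero_phase_difference(self):
        art = sd.ArtifactModel(field_amplitude_hz=0.0)
        fm = sd.synth_fieldmap(art, grid_shape=(12, 12, 12))
        assert np.all(fm.phase_te2 - fm.phase_te1 == 0.0)

    def test_phases_are_wrapped_and_truth_attached(self):
        art = sd.ArtifactModel(field_amplitude_hz=400.0,
                               reference_distance_mm=6.0, void_radius_mm=3.0)
        fm = sd.synth_fieldmap(art, grid_shape=(16, 16, 16))
        for ph in (fm.phase_te1, fm.phase_te2):
            assert np.all(ph > -np.pi - 1e-12) and np.all(ph <= np.pi + 1e-12)
        assert fm.offres_truth_hz is not None

    def test_projection_impulse_shift_and_normalization(self):
        frame = np.zeros((16, 20))
        frame[5, 11] = 3.0
        p0, p1 = sd.navigator_projections(frame)
        assert p0[5] == 1.0 and p1[11] == 1.0
        assert p0.sum() == pytest.approx(1.0) and p1.sum() == pytest.approx(1.0)
        shifted = np.roll(frame, 2, axis=0)
        q0, q1 = sd.navigator_projections(shifted)
        assert np.allclose(q0, np.roll(p0, 2))
        assert np.allclose(q1, p1)

    def test_zero_frame_projection_raises(self):
        with pytest.raises(DegenerateInputError):
            sd.navigator_projections(np.zeros((8, 8)))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(-50.0, 50.0), min_size=1, max_size=20),
       st.integers(-3, 3))
def test_wrap_phase_range_and_periodicity(values, k):
    phi = np.asarray(values)
    w = sd.wrap_phase(phi)
    assert np.all(w > -np.pi) and np.all(w <= np.pi)
    assert np.allclose(sd.wrap_phase(phi + 2 * np.pi * k), w, atol=1e-9)
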