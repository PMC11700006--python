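"""Divergence-curl registration: similarity, energy, recovery, tracking."""

import numpy as np
import pytest
from scipy import ndimage

from cardiotrack import gdc
from cardiotrack.containers import CineSeries
from cardiotrack.errors import ContractError, InvalidParameterError
from cardiotrack.gdc import ImagePair, RegistrationConfig, gdc_energy, lcc, register
from cardiotrack.synthdata import _composite, _disk


def naive_lcc(F, M, radius):
    """Per-pixel double-loop oracle for the squared local correlation
    (clipped disk neighbourhood, same variance floor as the module)."""
    h, w = F.shape
    out = np.zeros((h, w))
    floor_unit = 1e-8 * max(float(np.ptp(F)), float(np.ptp(M)), 1e-12) ** 2
    offsets = [(i, j) for i in range(-radius, radius + 1)
               for j in range(-radius, radius + 1) if i * i + j * j <= radius**2]
    for r in range(h):
        for c in range(w):
            fs, ms = [], []
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    fs.append(F[rr, cc])
                    ms.append(M[rr, cc])
            fs = np.asarray(fs)
            ms = np.asarray(ms)
            n = fs.size
            vf = np.sum((fs - fs.mean()) ** 2)
            vm = np.sum((ms - ms.mean()) ** 2)
            if vf <= floor_unit * n or vm <= floor_unit * n:
                continue
            cov = np.sum((fs - fs.mean()) * (ms - ms.mean()))
            out[r, c] = min(cov**2 / (vf * vm), 1.0)
    return out


def invert_field(ut, iters=25):
    """Numeric inverse of a displacement field by fixed-point iteration."""
    xx, yy = np.meshgrid(np.arange(ut.shape[1]), np.arange(ut.shape[2]),
                         indexing="ij")
    v = -ut.copy()
    for _ in range(iters):
        v = -np.stack([
            ndimage.map_coordinates(ut[c], [xx + v[0], yy + v[1]], order=1,
                                    mode="nearest")
            for c in range(2)
        ])
    return v


class TestLCC:
    def test_identical_images_give_unit_correlation(self, textured_image):
        m = lcc(textured_image, textured_image, 3)
        assert np.allclose(m, 1.0, atol=1e-10)

    def test_affine_intensity_invariance(self, textured_image):
        m = lcc(textured_image, 3.0 * textured_image + 7.0, 3)
        assert np.allclose(m, 1.0, atol=1e-10)

    def test_bounded_between_zero_and_one(self, rng):
        F = rng.normal(size=(32, 32))
        M = rng.normal(size=(32, 32))
        m = lcc(F, M, 3)
        assert m.min() >= 0.0 and m.max() <= 1.0

    def test_matches_naive_double_loop_oracle(self, rng):
        F = rng.normal(size=(32, 32))
        M = rng.normal(size=(32, 32))
        assert np.allclose(lcc(F, M, 3), naive_lcc(F, M, 3), atol=1e-10)

    def test_constant_region_maps_to_zero(self):
        F = np.zeros((20, 20))
        F[10:, :] = np.arange(20) * 0.1 + 1.0
        m = lcc(F, F.copy(), 3)
        assert np.all(m[:6, :] == 0.0)  # flat region: variance floor

    def test_oversized_radius_rejected(self, textured_image):
        with pytest.raises(InvalidParameterError):
            lcc(textured_image, textured_image, radius_px=40)


class TestEnergy:
    def test_identity_field_on_identical_images(self, textured_image):
        """With M = F and u = 0 every regularizer vanishes and the
        similarity contributes -1 per valid pixel."""
        pair = ImagePair(textured_image, textured_image)
        e, grad = gdc_energy(pair, np.zeros((2, 64, 64)))
        n_valid = int(np.sum(lcc(textured_image, textured_image, 3) > 0.5))
        assert e == pytest.approx(-n_valid, abs=1e-6)
        assert np.abs(grad).max() < 1e-6

    def test_constant_field_has_zero_regularizer_energy(self, textured_image, rng):
        """Regularizer terms are derivative-based, so a constant
        translation field costs nothing: switching the weights off does
        not change the energy."""
        pair = ImagePair(textured_image, np.roll(textured_image, 3, axis=0))
        u = np.ones((2, 64, 64)) * np.array([0.7, -1.3])[:, None, None]
        e_on, _ = gdc_energy(pair, u, RegistrationConfig())
        e_off, _ = gdc_energy(pair, u, RegistrationConfig(alpha=0, beta=0, gamma=0))
        assert e_on == pytest.approx(e_off, abs=1e-8)

    def test_rotation_field_curl_energy_closed_form(self, textured_image):
        """A linear rotation field u = omega(-y, x) has curl 2*omega
        everywhere; the curl term must equal gamma * (2 omega)^2 * N."""
        h = w = 64
        omega = 0.03
        rr, cc = np.meshgrid(np.arange(h, dtype=float),
                             np.arange(w, dtype=float), indexing="ij")
        u = np.stack([omega * (cc - w / 2), -omega * (rr - h / 2)])
        pair = ImagePair(textured_image, textured_image)
        gamma = 16.0
        e_curl, _ = gdc_energy(pair, u, RegistrationConfig(alpha=0, beta=0, gamma=gamma))
        e_none, _ = gdc_energy(pair, u, RegistrationConfig(alpha=0, beta=0, gamma=0))
        expected = gamma * (2 * omega) ** 2 * h * w
        assert (e_curl - e_none) == pytest.approx(expected, abs=1e-8)

    def test_difference_adjoint_is_exact_transpose(self, rng):
        """<D u, v> == <u, D^T v> for the discrete derivative operators
        used by all quadratic regularizer gradients."""
        for axis in (0, 1):
            u = rng.normal(size=(17, 13))
            v = rng.normal(size=(17, 13))
            lhs = np.sum(gdc._diff(u, axis) * v)
            rhs = np.sum(u * gdc._diff_adjoint(v, axis))
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_shape_mismatch_rejected(self, textured_image):
        with pytest.raises(ContractError):
            gdc_energy(ImagePair(textured_image, textured_image),
                       np.zeros((2, 10, 10)))


class TestRegister:
    def test_identity_recovery(self, textured_image):
        field = register(ImagePair(textured_image, textured_image))
        assert np.abs(field.u).max() < 0.05

    def test_translation_recovery(self, textured_image):
        M = ndimage.shift(textured_image, (2.0, -1.5), order=3, mode="nearest")
        field = register(ImagePair(textured_image, M))
        mask = textured_image > 0.2
        assert abs(field.u[0][mask].mean() - 2.0) < 0.3
        assert abs(field.u[1][mask].mean() + 1.5) < 0.3

    def test_smooth_warp_endpoint_error(self, textured_image, rng):
        """A smooth irrotational warp of up to 4 px is recovered with
        95th-percentile endpoint error below one pixel."""
        phi = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 8.0)
        ut = np.stack(np.gradient(phi))
        ut *= 4.0 / np.abs(ut).max()
        xx, yy = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        M = ndimage.map_coordinates(textured_image, [xx + ut[0], yy + ut[1]],
                                    order=3, mode="nearest")
        field = register(ImagePair(textured_image, M))
        err = np.sqrt(np.sum((field.u - invert_field(ut)) ** 2, axis=0))
        assert np.percentile(err, 95) < 1.0

    def test_curl_penalty_hurts_rotational_recovery(self, textured_image):
        """On a rotational warp the high curl penalty biases the
        solution; relaxing gamma recovers the field better."""
        h = w = 64
        rr, cc = np.meshgrid(np.arange(h, dtype=float),
                             np.arange(w, dtype=float), indexing="ij")
        taper = np.exp(-(((rr - 32) ** 2 + (cc - 32) ** 2) / (2 * 14.0**2)))
        omega = 0.06
        ut = np.stack([omega * (cc - 32) * taper, -omega * (rr - 32) * taper])
        xx, yy = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        M = ndimage.map_coordinates(textured_image, [xx + ut[0], yy + ut[1]],
                                    order=3, mode="nearest")
        v = invert_field(ut)
        errs = {}
        for gamma in (16.0, 0.01):
            field = register(ImagePair(textured_image, M),
                             RegistrationConfig(gamma=gamma))
            errs[gamma] = float(np.mean(np.sqrt(np.sum((field.u - v) ** 2, 0))))
        assert errs[0.01] < errs[16.0]

    def test_monotone_energy_across_levels(self, textured_image):
        """The returned field never has higher finest-level energy than
        the initialization."""
        M = ndimage.shift(textured_image, (1.0, 1.0), order=3, mode="nearest")
        pair = ImagePair(textured_image, M)
        cfg = RegistrationConfig()
        e0, _ = gdc_energy(pair, np.zeros((2, 64, 64)), cfg)
        field = register(pair, cfg)
        e1, _ = gdc_energy(pair, field.u, cfg)
        assert e1 <= e0


class TestTrackLandmarks:
    def test_static_cine_gives_constant_tracks(self):
        frame = _composite(np.full((48, 48), 0.1), _disk((48, 48), (24.0, 24.0), 8.0), 1.0)
        cine = CineSeries(np.stack([frame] * 4), (1.0, 1.0), 10.0, 100.0,
                          "coronal", ("HF", "RL"))
        tracks = gdc.track_landmarks(cine, np.array([[0.0, 0.0], [5.0, -3.0]]))
        for lm in tracks:
            assert np.abs(lm.pos_mm - lm.pos_mm[0]).max() < 0.05

    def test_translating_disk_center_follows_rendered_trajectory(self):
        frames, truth = [], []
        for k in range(8):
            c = np.array([32 + 0.6 * k, 32 - 0.4 * k])
            frames.append(_composite(np.full((64, 64), 0.1),
                                     _disk((64, 64), c, 6.0), 1.0))
            truth.append(c)
        cine = CineSeries(np.stack(frames), (1.0, 1.0), 10.0, 100.0,
                          "coronal", ("HF", "RL"))
        tracks = gdc.track_landmarks(cine, np.array([cine.px_to_mm(truth[0])]))
        est = np.stack([cine.mm_to_px(p) for p in tracks[0].pos_mm])
        assert np.abs(est - np.stack(truth)).max() < 0.3

    def test_lv_quadrant_tracking_subpixel_vs_truth(self, lv_tracked_small):
        """Propagated quadrant landmarks stay within one reconstructed
        pixel (RMS, in-plane) of the generator's ground truth."""
        px = lv_tracked_small["seq"].recon_pixel_mm
        for truth, track in zip(lv_tracked_small["truth"],
                                lv_tracked_small["tracks"]):
            err = np.sqrt(np.sum((track.pos_mm - truth.pos_mm) ** 2, axis=1))
            assert np.sqrt(np.mean(err**2)) < px
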