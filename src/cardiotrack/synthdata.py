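"""Synthetic inputs with the structure the analysis assumes.

This module generates every input the pipeline consumes:

* motion-phantom cines — an anti-aliased moving disk (the 3 cm spherical
  target of a Quasar-style motion phantom) on a static water-body
  background, driven by a cos^4 cardiac + sine respiratory trajectory;
* beating left-ventricle cines — a contracting myocardial annulus around
  a bright blood pool, translating with respiration, with ground-truth
  endocardial landmark tracks in the four LV quadrants;
* implanted-device artifacts — bSSFP off-resonance banding and
  gradient-echo signal voids from a dipole-like field perturbation;
* dual-echo 3D field-map volumes with known off-resonance ground truth;
* navigator projections — normalized 1D image profiles used as cheap
  real-time motion surrogates.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import PLANE_AXES, CineSeries, FieldMapVolume, LandmarkTrack, MotionTrace
from .errors import DegenerateInputError, ConfigurationError, InvalidParameterError, OutOfFieldError
from .params import SequenceParams, TrajectoryParams


# --------------------------------------------------------------------------
# phase helpers

def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase (radians) into ``(-pi, pi]``."""
    phi = np.asarray(phi, dtype=float)
    wrapped = phi - 2.0 * np.pi * np.round(phi / (2.0 * np.pi))
    # round-half-even can land exactly on -pi; fold that edge to +pi
    return np.where(wrapped <= -np.pi, wrapped + 2.0 * np.pi, wrapped)


# --------------------------------------------------------------------------
# device artifact model

@dataclass(frozen=True)
class ArtifactModel:
    """Dipole-like field perturbation of an implanted device or lead.

    The off-resonance follows an axial dipole pattern

        ``df(r, theta) = A * (d_ref / r)^3 * (3 cos^2(theta) - 1) / 2``

    with ``theta`` measured from the head-feet axis and ``r`` clipped at
    the void radius, so |df| decays monotonically (r^-3) along every ray
    beyond the signal void.  ``A`` is the peak offset at the reference
    distance on the device axis.  Inside ``void_radius_mm`` the signal is
    dropped to zero exactly (complete intravoxel dephasing).
    """

    device_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    field_amplitude_hz: float = 300.0
    reference_distance_mm: float = 10.0
    void_radius_mm: float = 6.0
    mode: str = "both"  # banding | void | both

    def __post_init__(self):
        if self.reference_distance_mm <= 0 or self.void_radius_mm < 0:
            raise InvalidParameterError("distances must be positive")
        if self.mode not in ("banding", "void", "both"):
            raise InvalidParameterError(f"unknown artifact mode {self.mode!r}")

    def offres_hz(self, points_mm: np.ndarray) -> np.ndarray:
        """Off-resonance (Hz) at 3D points, shape ``(..., 3)``, axes (HF, a1, a2)."""
        delta = np.asarray(points_mm, dtype=float) - np.asarray(self.device_center_mm)
        r = np.sqrt(np.sum(delta**2, axis=-1))
        r_eff = np.maximum(r, max(self.void_radius_mm, 1e-6))
        with np.errstate(invalid="ignore", divide="ignore"):
            cos_t = np.where(r_eff > 0, delta[..., 0] / np.maximum(r, 1e-12), 1.0)
        angular = 0.5 * (3.0 * cos_t**2 - 1.0)
        return self.field_amplitude_hz * (self.reference_distance_mm / r_eff) ** 3 * angular

    def offres_map_2d(self, shape, pixel_mm, plane_offset_mm: float = 0.0) -> np.ndarray:
        """Off-resonance sampled on an image plane a distance
        ``plane_offset_mm`` out of plane from the device."""
        rows, cols = _mm_grid(shape, pixel_mm)
        pts = np.stack(
            [rows, cols, np.full_like(rows, plane_offset_mm)], axis=-1
        )
        return self.offres_hz(pts)

    def void_mask_2d(self, shape, pixel_mm, plane_offset_mm: float = 0.0) -> np.ndarray:
        rows, cols = _mm_grid(shape, pixel_mm)
        d2 = (
            (rows - self.device_center_mm[0]) ** 2
            + (cols - self.device_center_mm[1]) ** 2
            + (plane_offset_mm - self.device_center_mm[2]) ** 2
        )
        return d2 <= self.void_radius_mm**2


def _mm_grid(shape, pixel_mm):
    """Row/col coordinate grids in mm relative to the image centre."""
    h, w = shape
    px = np.broadcast_to(np.asarray(pixel_mm, dtype=float), (2,))
    r = (np.arange(h) - (h - 1) / 2.0) * px[0]
    c = (np.arange(w) - (w - 1) / 2.0) * px[1]
    return np.meshgrid(r, c, indexing="ij")


# --------------------------------------------------------------------------
# trajectories

def make_trajectory(p: TrajectoryParams) -> MotionTrace:
    """Sample the phantom's cardiorespiratory trajectory.

    Returns a single-axis trace ``position(t) = cardiac(t) + resp(t)``
    sampled every ``p.sample_dt_ms``.  Requires the duration to cover at
    least one full respiratory period so that peak-to-peak statements
    about the waveform are meaningful.
    """
    resp_period_s = 60.0 / p.resp_rate_bpm
    if p.duration_s < resp_period_s:
        raise InvalidParameterError(
            f"duration {p.duration_s} s must cover one respiratory period "
            f"({resp_period_s} s)"
        )
    n = int(math.floor(p.duration_s * 1000.0 / p.sample_dt_ms)) + 1
    t_ms = np.arange(n) * p.sample_dt_ms
    pos = p.position(t_ms / 1000.0)
    return MotionTrace(t_ms, pos[:, None], (p.axis,), source="phantom_reference")


def cos4_phase(rate_bpm: float = 70.0):
    """Normalized cardiac contraction phase in [0, 1] (cos^4 pulse)."""
    if rate_bpm <= 0:
        raise InvalidParameterError("rate must be > 0")

    def phase(t_ms):
        t_s = np.asarray(t_ms, dtype=float) / 1000.0
        return np.cos(np.pi * t_s * rate_bpm / 60.0) ** 4

    return phase


# --------------------------------------------------------------------------
# rendering primitives

def _disk(shape, center_px, radius_px):
    """Anti-aliased disk coverage: linear partial-volume edge of ~1 px."""
    h, w = shape
    rr = np.arange(h)[:, None] - center_px[0]
    cc = np.arange(w)[None, :] - center_px[1]
    d = np.sqrt(rr**2 + cc**2)
    return np.clip(radius_px - d + 0.5, 0.0, 1.0)


def _ellipse(shape, center_px, semi_px):
    h, w = shape
    rr = (np.arange(h)[:, None] - center_px[0]) / semi_px[0]
    cc = (np.arange(w)[None, :] - center_px[1]) / semi_px[1]
    d = np.sqrt(rr**2 + cc**2)
    # feather over roughly one pixel of the tighter semi-axis
    return np.clip((1.0 - d) * min(semi_px) + 0.5, 0.0, 1.0)


def _composite(base, coverage, intensity):
    return base * (1.0 - coverage) + intensity * coverage


# --------------------------------------------------------------------------
# phantom cine

#: static scene intensities (arbitrary units, target normalized to 1)
_BODY_INT = 0.35
_STATIC_INSERT_INT = 0.55
_TARGET_INT = 1.0
_STATIC_INSERT_RADIUS_MM = 10.0
_STATIC_INSERT_OFFSET_MM = (0.0, -45.0)
_TARGET_BASE_OFFSET_MM = (0.0, 30.0)


def render_phantom_cine(
    traj: MotionTrace,
    seq: SequenceParams,
    sphere_diam_mm: float = 30.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    plane: str = "coronal",
    n_frames: int | None = None,
    latency_ms: float = 0.0,
) -> CineSeries:
    """Render the moving-sphere phantom as a cine series.

    Each frame shows the water-filled oval body, a static cylindrical
    insert, and the spherical target (drawn as its central-slice disk
    with an analytic partial-volume edge) displaced along the head-feet
    axis by the trajectory position at the frame's k-space-centre time.
    Additive Gaussian noise of ``noise_sd`` is applied per frame.

    ``latency_ms`` shifts the *reported* frame timestamps (``t0_ms``)
    to emulate the delay between k-space-centre acquisition and frame
    availability; the rendered content corresponds to acquisition time.
    """
    if sphere_diam_mm <= 0:
        raise InvalidParameterError("sphere diameter must be > 0")
    shape = seq.shape
    px = seq.recon_pixel_mm
    if n_frames is None:
        n_frames = int(np.floor((traj.t_ms[-1] - traj.t_ms[0]) / seq.t_scan_ms)) + 1
    t_frames = traj.t_ms[0] + np.arange(n_frames) * seq.t_scan_ms
    if t_frames[-1] > traj.t_ms[-1] + 1e-9:
        raise InvalidParameterError("trajectory shorter than requested cine duration")
    pos_hf = np.interp(t_frames, traj.t_ms, traj.pos_mm[:, 0])

    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    radius_px = 0.5 * sphere_diam_mm / px
    body = _ellipse(shape, center, (0.95 * shape[0] / 2.0, 0.95 * shape[1] / 2.0))
    static = _disk(
        shape,
        center + np.asarray(_STATIC_INSERT_OFFSET_MM) / px,
        _STATIC_INSERT_RADIUS_MM / px,
    )
    background = _composite(_composite(np.zeros(shape), body, _BODY_INT),
                            static, _STATIC_INSERT_INT)

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames,) + shape)
    base_off = np.asarray(_TARGET_BASE_OFFSET_MM)
    for k in range(n_frames):
        c_mm = base_off + np.array([pos_hf[k], 0.0])
        c_px = center + c_mm / px
        if (
            c_px[0] - radius_px < -0.5 or c_px[1] - radius_px < -0.5
            or c_px[0] + radius_px > shape[0] - 0.5
            or c_px[1] + radius_px > shape[1] - 0.5
        ):
            raise OutOfFieldError(
                f"target leaves the field of view at frame {k} "
                f"(centre {c_mm} mm)", frame=k,
            )
        frame = _composite(background, _disk(shape, c_px, radius_px), _TARGET_INT)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=shape)
        frames[k] = frame

    frames = np.clip(frames, 0.0, None)
    return CineSeries(
        frames=frames,
        pixel_mm=(px, px),
        slice_mm=seq.acq_voxel_mm[2],
        dt_ms=seq.t_scan_ms,
        orientation=plane,
        axes=PLANE_AXES[plane],
        t0_ms=float(traj.t_ms[0] + latency_ms),
    )


def phantom_truth_trace(traj: MotionTrace, cine: CineSeries) -> MotionTrace:
    """Ground-truth in-plane target positions at the cine's acquisition
    times (both in-plane axes; the transverse axis is static)."""
    t_acq = traj.t_ms[0] + np.arange(cine.n_frames) * cine.dt_ms
    hf = np.interp(t_acq, traj.t_ms, traj.pos_mm[:, 0]) + _TARGET_BASE_OFFSET_MM[0]
    other = np.full_like(hf, _TARGET_BASE_OFFSET_MM[1])
    return MotionTrace(t_acq, np.stack([hf, other], axis=1), cine.axes,
                       source="phantom_reference")


# --------------------------------------------------------------------------
# left-ventricle cine

#: default LV geometry (mm); endocardial radius, wall thickness, and the
#: fraction of the endocardial excursion seen by the epicardium (the wall
#: thickens during systole, so the outer edge moves less than the inner).
_LV_R_ENDO_MM = 20.0
_LV_WALL_MM = 9.0
_LV_EPI_FRACTION = 0.55
_LV_QUADRANT_ANGLES = (45.0, 135.0, 225.0, 315.0)

#: sequence-dependent contrast: blood pool > myocardium > background for
#: bSSFP; reduced pool/myocardium contrast and lower SNR for T1-GRE.
_LV_CONTRAST = {
    "bSSFP": dict(pool=1.0, myo=0.5, body=0.25, noise_sd=0.02),
    "T1-GRE": dict(pool=0.55, myo=0.42, body=0.25, noise_sd=0.06),
}


def render_lv_cine(
    traj_resp: MotionTrace,
    cardiac_phase_fn,
    seq: SequenceParams,
    artifact: ArtifactModel | None = None,
    seed: int = 0,
    n_frames: int | None = None,
    contraction_p2p_mm: float = 8.0,
    plane: str = "coronal",
    noise_sd: float | None = None,
) -> tuple[CineSeries, list[LandmarkTrack]]:
    """Render a beating-LV cine and its ground-truth landmark tracks.

    The LV is modelled as a myocardial annulus around a bright blood
    pool.  The endocardial radius contracts by ``contraction_p2p_mm *
    cardiac_phase_fn(t)`` (phase in [0, 1]) and the whole structure
    translates along the head-feet axis with the respiratory trace.
    Returns the cine plus four endocardial landmark tracks, one per LV
    quadrant (quadrants split by the image axes through the LV centre).
    """
    if seq.name not in _LV_CONTRAST:
        raise ConfigurationError(f"unknown sequence name {seq.name!r}")
    look = _LV_CONTRAST[seq.name]
    if noise_sd is None:
        noise_sd = look["noise_sd"]

    shape = seq.shape
    px = seq.recon_pixel_mm
    if n_frames is None:
        n_frames = int(np.floor((traj_resp.t_ms[-1] - traj_resp.t_ms[0]) / seq.t_scan_ms)) + 1
    t_frames = traj_resp.t_ms[0] + np.arange(n_frames) * seq.t_scan_ms
    resp = np.interp(t_frames, traj_resp.t_ms, traj_resp.pos_mm[:, 0])
    resp = resp - resp.mean()  # keep the LV centred over the series
    phase = np.clip(np.asarray(cardiac_phase_fn(t_frames), dtype=float), 0.0, 1.0)

    center_img = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    body = _ellipse(shape, center_img, (0.92 * shape[0] / 2.0, 0.92 * shape[1] / 2.0))
    background = _composite(np.zeros(shape), body, look["body"])

    if artifact is not None:
        offres = artifact.offres_map_2d(shape, (px, px))
        void = artifact.void_mask_2d(shape, (px, px))
    angles = np.deg2rad(_LV_QUADRANT_ANGLES)
    dirs = np.stack([-np.cos(angles), np.sin(angles)], axis=1)  # (4, 2) row/col

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames,) + shape)
    truth = np.empty((4, n_frames, 2))
    for k in range(n_frames):
        c_mm = np.array([resp[k], 0.0])
        c_px = center_img + c_mm / px
        r_endo = _LV_R_ENDO_MM - contraction_p2p_mm * phase[k]
        r_epi = (_LV_R_ENDO_MM + _LV_WALL_MM
                 - _LV_EPI_FRACTION * contraction_p2p_mm * phase[k])
        if r_endo <= 2.0:
            raise InvalidParameterError("contraction collapses the blood pool")
        frame = _composite(background, _disk(shape, c_px, r_epi / px), look["myo"])
        frame = _composite(frame, _disk(shape, c_px, r_endo / px), look["pool"])
        if artifact is not None:
            frame = _apply_artifact_frame(frame, seq, offres, void, artifact.mode, px)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=shape)
        frames[k] = frame
        truth[:, k, :] = c_mm[None, :] + r_endo * dirs

    frames = np.clip(frames, 0.0, None)
    cine = CineSeries(
        frames=frames, pixel_mm=(px, px), slice_mm=seq.acq_voxel_mm[2],
        dt_ms=seq.t_scan_ms, orientation=plane, axes=PLANE_AXES[plane],
        t0_ms=float(t_frames[0]),
    )
    tracks = [
        LandmarkTrack(name=f"quadrant_{q + 1}", t_ms=t_frames,
                      pos_mm=truth[q], axes=PLANE_AXES[plane])
        for q in range(4)
    ]
    return cine, tracks


# --------------------------------------------------------------------------
# CIED artifacts

def bssfp_attenuation(offres_hz: np.ndarray, tr_ms: float) -> np.ndarray:
    """Banding attenuation factor ``|cos(pi * df * TR)|``.

    Dark bands appear where the per-TR off-resonance phase accrual
    approaches pi, i.e. at ``df = (2k+1) / (2 TR)``.
    """
    return np.abs(np.cos(np.pi * np.asarray(offres_hz, dtype=float) * tr_ms / 1000.0))


def gre_dephasing_attenuation(
    offres_hz: np.ndarray, te_ms: float, pixel_mm, k: float = 1.0
) -> np.ndarray:
    """Mild intravoxel-dephasing attenuation for spoiled gradient echo.

    Approximated as ``exp(-|grad df| * voxel * TE * k)`` with the field
    gradient in Hz/mm; strictly positive, so the gradient-echo image has
    no zero-signal band outside the void.
    """
    px = np.broadcast_to(np.asarray(pixel_mm, dtype=float), (2,))
    g0, g1 = np.gradient(np.asarray(offres_hz, dtype=float))
    grad_mag = np.sqrt((g0 / px[0]) ** 2 + (g1 / px[1]) ** 2)
    voxel = float(np.mean(px))
    return np.exp(-grad_mag * voxel * te_ms / 1000.0 * k)


def _apply_artifact_frame(frame, seq, offres, void, mode, px):
    out = frame.copy()
    if seq.name == "bSSFP":
        if mode in ("banding", "both"):
            out = out * bssfp_attenuation(offres, seq.tr_ms)
    elif seq.name == "T1-GRE":
        out = out * gre_dephasing_attenuation(offres, seq.te_ms, (px, px))
    else:
        raise ConfigurationError(f"unknown sequence name {seq.name!r}")
    if mode in ("void", "both") or seq.name == "T1-GRE":
        out[void] = 0.0
    return out


def apply_cied_artifact(
    cine: CineSeries, seq: SequenceParams, artifact: ArtifactModel
) -> CineSeries:
    """Superimpose device-induced artifacts on every frame of a cine.

    bSSFP frames are modulated by the banding attenuation of the
    device's off-resonance map; gradient-echo frames only suffer a
    signal void plus mild dephasing nearby.  Both modes zero the void.
    """
    if seq.name not in ("bSSFP", "T1-GRE"):
        raise ConfigurationError(f"unknown sequence name {seq.name!r}")
    offres = artifact.offres_map_2d(cine.shape, cine.pixel_mm)
    void = artifact.void_mask_2d(cine.shape, cine.pixel_mm)
    frames = np.stack([
        _apply_artifact_frame(f, seq, offres, void, artifact.mode, cine.pixel_mm[0])
        for f in cine.frames
    ])
    return CineSeries(frames, cine.pixel_mm, cine.slice_mm, cine.dt_ms,
                      cine.orientation, cine.axes, cine.t0_ms)


# --------------------------------------------------------------------------
# field-map volumes

def synth_fieldmap(
    artifact: ArtifactModel,
    grid_shape=(40, 40, 40),
    voxel_mm=(2.0, 2.0, 2.0),
    dte_ms: float = 4.6,
    te1_ms: float = 4.6,
    wrap: bool = True,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FieldMapVolume:
    """Synthesize a dual-echo gradient-echo volume around a device.

    The ground-truth off-resonance is the artifact's dipole field;
    phases are ``2*pi*f*TE`` wrapped into ``(-pi, pi]`` (or left
    unwrapped when ``wrap=False``, useful for oracle tests).  The
    magnitude is high inside an ellipsoidal body mask and near zero in
    air and in the device's signal void.  The truth is attached as
    ``offres_truth_hz`` so processing chains can be validated round-trip.
    """
    if dte_ms <= 0:
        raise InvalidParameterError("dte_ms must be > 0")
    shape = tuple(grid_shape)
    vx = np.asarray(voxel_mm, dtype=float)
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * v for n, v in zip(shape, vx)
    ]
    grid = np.stack(np.meshgrid(*coords, indexing="ij"), axis=-1)
    truth = artifact.offres_hz(grid)

    rng = np.random.default_rng(seed)
    d = np.sqrt(np.sum((grid - np.asarray(artifact.device_center_mm)) ** 2, axis=-1))
    body = np.sqrt(np.sum((grid / (0.45 * vx * np.asarray(shape))) ** 2, axis=-1)) <= 1.0
    magnitude = np.where(body, 1.0, 0.02)
    magnitude[d <= artifact.void_radius_mm] = 0.0
    if noise_sd > 0:
        magnitude = np.clip(magnitude + rng.normal(0.0, noise_sd, shape), 0.0, None)

    phase1 = 2.0 * np.pi * truth * te1_ms / 1000.0
    phase2 = 2.0 * np.pi * truth * (te1_ms + dte_ms) / 1000.0
    if noise_sd > 0:
        phase_noise = noise_sd / np.maximum(magnitude, 0.05)
        phase1 = phase1 + rng.normal(0.0, 1.0, shape) * phase_noise
        phase2 = phase2 + rng.normal(0.0, 1.0, shape) * phase_noise
    if wrap:
        phase1, phase2 = wrap_phase(phase1), wrap_phase(phase2)
    return FieldMapVolume(
        magnitude=magnitude, phase_te1=phase1, phase_te2=phase2,
        dte_ms=dte_ms, voxel_mm=tuple(vx), offres_truth_hz=truth,
    )


# --------------------------------------------------------------------------
# navigator projections

def navigator_projections(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized 1D profiles of a frame along each image axis.

    Returns ``(p0, p1)`` where ``p0[i] = sum_j frame[i, j]`` (profile
    along axis 0) and ``p1[j] = sum_i frame[i, j]``, each scaled to unit
    total.  By the projection-slice theorem these are equivalent to the
    central k-space lines used as navigator readouts.
    """
    frame = np.asarray(frame, dtype=float)
    total = frame.sum()
    if total <= 0:
        raise DegenerateInputError("cannot project an all-zero frame")
    return frame.sum(axis=1) / total, frame.sum(axis=0) / total
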