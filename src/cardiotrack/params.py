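"""Acquisition and motion-trajectory parameter types.

``SequenceParams`` carries the acquisition metadata of the two cine
sequences used for real-time cardiac imaging on a 1.5 T MR-linac: a
balanced SSFP sequence (high blood/myocardium contrast, banding-prone,
high readout bandwidth) and a spoiled gradient-echo sequence (lower
SNR/contrast, robust near metal, low bandwidth).  The bandwidth and
acquisition voxel drive both the banding-artifact simulation and the
conversion of off-resonance (Hz) to spatial distortion (mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class SequenceParams:
    """Cine acquisition metadata.

    Parameters
    ----------
    name
        Sequence label, ``"bSSFP"`` or ``"T1-GRE"``.
    tr_ms, te_ms
        Repetition / echo time in milliseconds.
    flip_deg
        Excitation flip angle in degrees.
    bw_hz_per_px
        Readout bandwidth per acquisition pixel (Hz/px).  An off-resonance
        offset of ``f`` Hz displaces signal by ``f / bw_hz_per_px``
        acquisition pixels along the readout axis.
    acq_voxel_mm
        Acquired voxel size ``(readout, phase, slice)`` in mm.
    recon_pixel_mm
        Reconstructed in-plane pixel size in mm (isotropic in-plane).
    fov_mm
        In-plane field of view ``(axis0, axis1)`` in mm.
    t_scan_ms
        Temporal resolution: time between successive cine frames.
    readout_axis
        Anatomical label of the readout direction (head-feet here).
    matrix
        Reconstructed matrix size; derived from ``fov_mm`` and
        ``recon_pixel_mm`` when omitted.
    """

    name: str
    tr_ms: float
    te_ms: float
    flip_deg: float
    bw_hz_per_px: float
    acq_voxel_mm: tuple[float, float, float]
    recon_pixel_mm: float
    fov_mm: tuple[float, float]
    t_scan_ms: float
    readout_axis: str = "HF"
    matrix: tuple[int, int] | None = None

    def __post_init__(self):
        positives = {
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "flip_deg": self.flip_deg,
            "bw_hz_per_px": self.bw_hz_per_px,
            "recon_pixel_mm": self.recon_pixel_mm,
            "t_scan_ms": self.t_scan_ms,
        }
        for key, value in positives.items():
            if not value > 0:
                raise InvalidParameterError(f"{key} must be > 0, got {value!r}")
        if any(v <= 0 for v in self.acq_voxel_mm) or any(v <= 0 for v in self.fov_mm):
            raise InvalidParameterError("voxel and FOV entries must be > 0")
        if not self.te_ms < self.tr_ms:
            raise InvalidParameterError(
                f"te_ms ({self.te_ms}) must be smaller than tr_ms ({self.tr_ms})"
            )
        if self.recon_pixel_mm > min(self.acq_voxel_mm[:2]) + 1e-12:
            raise InvalidParameterError(
                "reconstructed pixel must not exceed the acquired in-plane voxel"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """Reconstructed image matrix (rows, cols)."""
        if self.matrix is not None:
            return self.matrix
        return (
            int(round(self.fov_mm[0] / self.recon_pixel_mm)),
            int(round(self.fov_mm[1] / self.recon_pixel_mm)),
        )


#: Presets for the four cine geometries: (sequence name, plane) -> params.
_PRESETS = {
    ("bSSFP", "coronal"): dict(
        name="bSSFP", tr_ms=2.8, te_ms=1.4, flip_deg=50.0, bw_hz_per_px=1884.0,
        acq_voxel_mm=(3.0, 3.0, 10.0), recon_pixel_mm=2.6, fov_mm=(250.0, 250.0),
        t_scan_ms=96.0, matrix=(96, 96),
    ),
    ("bSSFP", "sagittal"): dict(
        name="bSSFP", tr_ms=2.8, te_ms=1.4, flip_deg=50.0, bw_hz_per_px=1884.0,
        acq_voxel_mm=(3.0, 3.0, 10.0), recon_pixel_mm=2.2, fov_mm=(280.0, 158.0),
        t_scan_ms=96.0, matrix=(127, 71),
    ),
    ("T1-GRE", "coronal"): dict(
        name="T1-GRE", tr_ms=2.6, te_ms=1.4, flip_deg=10.0, bw_hz_per_px=500.0,
        acq_voxel_mm=(4.0, 4.0, 10.0), recon_pixel_mm=3.2, fov_mm=(225.0, 225.0),
        t_scan_ms=97.0, matrix=(70, 70),
    ),
    ("T1-GRE", "sagittal"): dict(
        name="T1-GRE", tr_ms=2.6, te_ms=1.4, flip_deg=10.0, bw_hz_per_px=500.0,
        acq_voxel_mm=(4.0, 4.0, 10.0), recon_pixel_mm=3.2, fov_mm=(225.0, 178.0),
        t_scan_ms=97.0, matrix=(70, 56),
    ),
}


def sequence_preset(name: str, plane: str) -> SequenceParams:
    """Return the acquisition preset for ``name`` in ``plane``.

    ``name`` is ``"bSSFP"`` or ``"T1-GRE"``; ``plane`` is ``"coronal"``
    or ``"sagittal"``.
    """
    try:
        return SequenceParams(**_PRESETS[(name, plane)])
    except KeyError:
        raise InvalidParameterError(
            f"unknown sequence preset {(name, plane)!r}; "
            f"valid keys: {sorted(_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class TrajectoryParams:
    """Artificial cardiorespiratory trajectory of the motion phantom.

    The target moves along a single (head-feet) axis as the sum of a
    pulse-like cardiac component, ``p2p * cos^4(pi * t * rate/60)``
    (nonnegative, range ``[0, p2p]``), and a centred respiratory sine,
    ``(p2p/2) * sin(2*pi* t * rate/60)``.
    """

    cardiac_shape: str = "cos4"
    cardiac_rate_bpm: float = 70.0
    cardiac_p2p_mm: float = 10.0
    resp_shape: str = "sine"
    resp_rate_bpm: float = 12.0
    resp_p2p_mm: float = 20.0
    axis: str = "HF"
    duration_s: float = 20.0
    sample_dt_ms: float = 10.0

    def __post_init__(self):
        if self.cardiac_shape != "cos4" or self.resp_shape != "sine":
            raise InvalidParameterError(
                "supported waveforms are cardiac='cos4' and resp='sine'"
            )
        if self.cardiac_p2p_mm < 0 or self.resp_p2p_mm < 0:
            raise InvalidParameterError("amplitudes must be >= 0")
        if self.cardiac_rate_bpm <= 0 or self.resp_rate_bpm <= 0:
            raise InvalidParameterError("rates must be > 0")
        if self.duration_s <= 0 or self.sample_dt_ms <= 0:
            raise InvalidParameterError("duration and sampling step must be > 0")

    def cardiac_waveform(self, t_s: np.ndarray) -> np.ndarray:
        """Cardiac displacement (mm) at time ``t_s`` (seconds)."""
        t_s = np.asarray(t_s, dtype=float)
        return self.cardiac_p2p_mm * np.cos(
            np.pi * t_s * self.cardiac_rate_bpm / 60.0
        ) ** 4

    def resp_waveform(self, t_s: np.ndarray) -> np.ndarray:
        """Respiratory displacement (mm) at time ``t_s`` (seconds)."""
        t_s = np.asarray(t_s, dtype=float)
        return 0.5 * self.resp_p2p_mm * np.sin(
            2.0 * np.pi * t_s * self.resp_rate_bpm / 60.0
        )

    def position(self, t_s: np.ndarray) -> np.ndarray:
        """Total displacement (mm): cardiac + respiratory."""
        return self.cardiac_waveform(t_s) + self.resp_waveform(t_s)
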