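"""In-memory containers shared across the pipeline.

Conventions
-----------
* Image indices are ``(row, col)``, 0-based; physical in-plane positions
  are in mm relative to the grid centre ``((H-1)/2, (W-1)/2)``.
* Coronal images use anatomical axes ``("HF", "RL")`` (head-feet,
  right-left); sagittal images ``("HF", "AP")``.  The head-feet axis is
  always image axis 0, matching the readout direction.
* Motion traces store positions in mm with labelled axes and strictly
  increasing timestamps in ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, InvalidParameterError

PLANE_AXES = {"coronal": ("HF", "RL"), "sagittal": ("HF", "AP")}


@dataclass
class MotionTrace:
    """Per-sample positions (mm) of a target or landmark over time.

    ``pos_mm`` has shape ``(n, k)`` with one column per labelled axis.
    ``valid`` marks samples usable for metrics; invalid samples may hold
    NaN positions (e.g. a frame where detection failed).
    """

    t_ms: np.ndarray
    pos_mm: np.ndarray
    axes: tuple[str, ...]
    source: str = "image_derived"
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.pos_mm = np.atleast_2d(np.asarray(self.pos_mm, dtype=float))
        if self.pos_mm.shape[0] != self.t_ms.shape[0]:
            self.pos_mm = self.pos_mm.T
        if self.pos_mm.shape != (self.t_ms.size, len(self.axes)):
            raise ContractError(
                f"pos_mm shape {self.pos_mm.shape} inconsistent with "
                f"{self.t_ms.size} samples and axes {self.axes}"
            )
        if self.t_ms.size > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise InvalidParameterError("timestamps must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.t_ms.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if not np.all(np.isfinite(self.pos_mm[self.valid])):
            raise InvalidParameterError("positions of valid samples must be finite")

    def __len__(self) -> int:
        return self.t_ms.size

    def axis(self, label: str) -> np.ndarray:
        """Position column for the given anatomical axis label."""
        try:
            return self.pos_mm[:, self.axes.index(label)]
        except ValueError:
            raise ContractError(f"trace has no axis {label!r}; axes={self.axes}") from None

    def shifted(self, dt_ms: float) -> "MotionTrace":
        """Copy of the trace with all timestamps translated by ``dt_ms``."""
        return MotionTrace(self.t_ms + dt_ms, self.pos_mm.copy(), self.axes,
                           self.source, self.valid.copy())


@dataclass
class CineSeries:
    """Time-ordered stack of 2D frames with spacing and timing metadata."""

    frames: np.ndarray  # (T, H, W)
    pixel_mm: tuple[float, float]
    slice_mm: float
    dt_ms: float
    orientation: str  # "coronal" | "sagittal"
    axes: tuple[str, str]
    t0_ms: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ContractError("frames must be a (T, H, W) array")
        if min(self.pixel_mm) <= 0 or self.dt_ms <= 0 or self.slice_mm <= 0:
            raise InvalidParameterError("pixel_mm, slice_mm and dt_ms must be > 0")
        if not np.all(np.isfinite(self.frames)) or np.min(self.frames) < 0:
            raise InvalidParameterError("frame intensities must be finite and >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times_ms(self) -> np.ndarray:
        """Timestamp (k-space centre) of every frame."""
        return self.t0_ms + np.arange(self.n_frames) * self.dt_ms

    # mm <-> pixel conversions (mm measured from the grid centre)
    @property
    def center_px(self) -> np.ndarray:
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0

    def mm_to_px(self, pos_mm: np.ndarray) -> np.ndarray:
        pos_mm = np.asarray(pos_mm, dtype=float)
        return self.center_px + pos_mm / np.asarray(self.pixel_mm)

    def px_to_mm(self, pos_px: np.ndarray) -> np.ndarray:
        pos_px = np.asarray(pos_px, dtype=float)
        return (pos_px - self.center_px) * np.asarray(self.pixel_mm)


@dataclass
class LandmarkTrack:
    """Per-frame 2D positions (mm) of one named landmark."""

    name: str
    t_ms: np.ndarray
    pos_mm: np.ndarray  # (T, 2)
    axes: tuple[str, str]
    valid: np.ndarray | None = None

    def __post_init__(self):
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.pos_mm = np.asarray(self.pos_mm, dtype=float)
        if self.pos_mm.shape != (self.t_ms.size, 2):
            raise ContractError("pos_mm must be (n_frames, 2)")
        if self.valid is None:
            self.valid = np.ones(self.t_ms.size, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def as_trace(self, source: str = "image_derived") -> MotionTrace:
        return MotionTrace(self.t_ms, self.pos_mm, self.axes, source, self.valid)


@dataclass
class DeformationField:
    """Dense displacement field mapping fixed -> moving coordinates.

    ``u`` has shape ``(2, H, W)`` in pixel units: a point at fixed-image
    index ``x`` corresponds to ``x + u[:, x]`` in the moving image.  The
    identity transform is ``u == 0`` everywhere.
    """

    u: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 3 or self.u.shape[0] != 2:
            raise ContractError("u must have shape (2, H, W)")
        if not np.all(np.isfinite(self.u)):
            raise InvalidParameterError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[1:]

    def u_mm(self) -> np.ndarray:
        """Displacements in mm."""
        sp = np.asarray(self.spacing_mm, dtype=float)
        return self.u * sp[:, None, None]

    @classmethod
    def identity(cls, shape, spacing_mm=(1.0, 1.0)) -> "DeformationField":
        return cls(np.zeros((2, *shape)), spacing_mm)


@dataclass
class FieldMapVolume:
    """Dual-echo phase data and derived off-resonance on a 3D grid.

    Phases are stored wrapped to ``(-pi, pi]``.  ``offres_hz`` is filled
    by the field-map processing chain; generators may attach the known
    ground truth as ``offres_truth_hz`` for validation.
    """

    magnitude: np.ndarray
    phase_te1: np.ndarray
    phase_te2: np.ndarray
    dte_ms: float
    voxel_mm: tuple[float, float, float]
    offres_hz: np.ndarray | None = None
    offres_truth_hz: np.ndarray | None = None

    def __post_init__(self):
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase_te1 = np.asarray(self.phase_te1, dtype=float)
        self.phase_te2 = np.asarray(self.phase_te2, dtype=float)
        if self.dte_ms <= 0:
            raise InvalidParameterError("dte_ms must be > 0")
        if not (self.magnitude.shape == self.phase_te1.shape == self.phase_te2.shape):
            raise ContractError("magnitude and phase arrays must share one shape")
        for ph in (self.phase_te1, self.phase_te2):
            if np.any(ph <= -np.pi - 1e-9) or np.any(ph > np.pi + 1e-9):
                raise InvalidParameterError("phases must be wrapped to (-pi, pi]")

    @property
    def shape(self):
        return self.magnitude.shape


@dataclass
class TrackingResult:
    """Outcome of tracking one phantom cine against its reference."""

    trace: MotionTrace
    latency_ms: float
    rmse_mm: dict  # per-axis label -> RMSE, plus "2D"
    upsample_factor: int

    def __post_init__(self):
        for key, value in self.rmse_mm.items():
            if value < 0:
                raise InvalidParameterError(f"rmse_mm[{key!r}] must be >= 0")


@dataclass
class ShellSet:
    """Concentric shells around a base mask at increasing margins (mm)."""

    base_mask: np.ndarray
    margins_mm: tuple[float, ...]
    shells: list  # list of boolean arrays, one per margin

    def union(self) -> np.ndarray:
        out = np.zeros_like(self.base_mask, dtype=bool)
        for s in self.shells:
            out |= s
        return out


@dataclass
class ComparisonReport:
    """Validation statistics comparing two motion traces."""

    axes: tuple[str, ...]
    pwd_per_axis: dict
    pwd_2d: np.ndarray
    rmsd_per_axis: dict
    rmsd_2d: float
    wilcoxon_p: float
    outlier_fraction: float
    n: int

    def to_dict(self) -> dict:
        return {
            "axes": list(self.axes),
            "rmsd_per_axis": {k: float(v) for k, v in self.rmsd_per_axis.items()},
            "rmsd_2d": float(self.rmsd_2d),
            "wilcoxon_p": float(self.wilcoxon_p),
            "outlier_fraction": float(self.outlier_fraction),
            "n": int(self.n),
        }
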