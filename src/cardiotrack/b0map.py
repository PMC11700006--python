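"""Static-field mapping and geometric-distortion analysis.

Chain: dual-echo phase volumes -> wrapped phase difference -> quality-
guided region-growing unwrapping -> off-resonance map (Hz) -> shells or
anatomical structure masks -> expected spatial distortion (mm) per cine
sequence.  The distortion conversion is the readout-axis pixel shift

    distortion_mm = offres_hz / bw_hz_per_px * acq_voxel_readout_mm

so a low-bandwidth gradient-echo sequence distorts several times more
than a high-bandwidth bSSFP sequence for identical field offsets.
"""

from __future__ import annotations

import heapq
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import FieldMapVolume, ShellSet
from .errors import InvalidParameterError
from .params import SequenceParams
from .synthdata import wrap_phase

__all__ = [
    "phase_to_offres",
    "unwrap_region_growing",
    "make_shells",
    "offres_to_distortion",
    "structure_stats",
]


def phase_to_offres(fm: FieldMapVolume, unwrap: bool = False) -> np.ndarray:
    """Off-resonance map (Hz) from the dual-echo phase difference.

    ``df = wrap(phase_te2 - phase_te1) / (2 pi dTE)``; unambiguous for
    offsets within the Nyquist band ``|df| < 1/(2 dTE)`` (about
    108.7 Hz at dTE = 4.6 ms).  With ``unwrap=True`` the wrapped
    difference is first unwrapped by region growing on the magnitude.
    """
    dphi = wrap_phase(fm.phase_te2 - fm.phase_te1)
    if unwrap:
        dphi = unwrap_region_growing(dphi, fm.magnitude)
    offres = dphi / (2.0 * np.pi * fm.dte_ms / 1000.0)
    fm.offres_hz = offres
    return offres


def unwrap_region_growing(
    wrapped: np.ndarray,
    magnitude: np.ndarray,
    seed_voxel: tuple | None = None,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Quality-guided region-growing phase unwrapping.

    Voxels are visited in descending-magnitude priority order starting
    from the highest-magnitude voxel (or a given seed), growing over
    face-connected neighbours.  Each voxel gets the integer multiple of
    2 pi that brings it closest to the mean of its already-unwrapped
    neighbours.  The result is continuous up to one global 2 pi k offset
    per connected region; disconnected regions are unwrapped
    independently with a warning.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    magnitude = np.asarray(magnitude, dtype=float)
    if wrapped.shape != magnitude.shape:
        raise InvalidParameterError("wrapped map and magnitude must share one shape")
    if mask is None:
        mask = np.ones(wrapped.shape, dtype=bool)
    out = wrapped.copy()
    visited = ~np.asarray(mask, dtype=bool)
    offsets = _face_neighbours(wrapped.ndim)
    counter = 0

    n_components = 0
    while not visited.all():
        remaining = ~visited
        if seed_voxel is not None and n_components == 0:
            seed = tuple(seed_voxel)
        else:
            flat = np.where(remaining.ravel())[0]
            seed = np.unravel_index(flat[np.argmax(magnitude.ravel()[flat])],
                                    wrapped.shape)
        n_components += 1
        heap = [(-magnitude[seed], counter, seed)]
        counter += 1
        queued = np.zeros_like(visited)
        queued[seed] = True
        while heap:
            _, _, idx = heapq.heappop(heap)
            if visited[idx]:
                continue
            nb_vals = []
            for off in offsets:
                nb = tuple(i + o for i, o in zip(idx, off))
                if all(0 <= i < s for i, s in zip(nb, wrapped.shape)):
                    if visited[nb] and mask[nb]:
                        nb_vals.append(out[nb])
            if nb_vals:
                target = float(np.mean(nb_vals))
                k = np.round((target - wrapped[idx]) / (2.0 * np.pi))
                out[idx] = wrapped[idx] + 2.0 * np.pi * k
            visited[idx] = True
            for off in offsets:
                nb = tuple(i + o for i, o in zip(idx, off))
                if (all(0 <= i < s for i, s in zip(nb, wrapped.shape))
                        and not visited[nb] and not queued[nb]):
                    heapq.heappush(heap, (-magnitude[nb], counter, nb))
                    counter += 1
                    queued[nb] = True
    if n_components > 1:
        warnings.warn(
            f"foreground has {n_components} connected components; each was "
            "unwrapped independently"
        )
    return out


def _face_neighbours(ndim: int):
    offs = []
    for axis in range(ndim):
        for sign in (-1, 1):
            off = [0] * ndim
            off[axis] = sign
            offs.append(tuple(off))
    return offs


def make_shells(
    mask: np.ndarray, margins_mm, voxel_mm=(1.0, 1.0, 1.0)
) -> ShellSet:
    """Concentric shells around a mask at the given margins (mm).

    ``shell_k = dilate(mask, margin_k) \\ dilate(mask, margin_{k-1})``
    (the first shell is taken against the mask itself); dilation is by
    thresholding the Euclidean distance transform, so anisotropic voxels
    are handled in physical units.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidParameterError("base mask is empty")
    margins = [float(m) for m in margins_mm]
    if margins != sorted(margins) or margins[0] <= 0:
        raise InvalidParameterError("margins must be positive and ascending")
    dist = ndimage.distance_transform_edt(~mask, sampling=voxel_mm)
    shells = []
    prev = mask
    for m in margins:
        dilated = dist <= m  # includes the mask (distance 0)
        shells.append(dilated & ~prev)
        prev = dilated
    return ShellSet(base_mask=mask, margins_mm=tuple(margins), shells=shells)


def offres_to_distortion(offres_hz, seq: SequenceParams):
    """Expected readout-axis spatial distortion (mm) of field offsets.

    Sign-preserving; applied along the readout (head-feet) axis only,
    using the acquisition voxel (bandwidth is per acquisition pixel).
    """
    if seq.bw_hz_per_px <= 0:
        raise InvalidParameterError("bandwidth must be > 0")
    return np.asarray(offres_hz, dtype=float) / seq.bw_hz_per_px * seq.acq_voxel_mm[0]


def structure_stats(
    offres_hz: np.ndarray,
    masks: dict,
    sequences: list,
) -> pd.DataFrame:
    """Per-structure, per-sequence offset and distortion statistics.

    For every named mask and sequence: mean, SD and the central 98%
    interval (1st-99th percentile) of the frequency offsets (Hz) and of
    the converted spatial distortions (mm).  Empty masks are reported
    as missing (NaN statistics), not as zeros.
    """
    rows = []
    for sname, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        values = np.asarray(offres_hz)[mask]
        for seq in sequences:
            row = {"structure": sname, "sequence": seq.name, "n_voxels": int(values.size)}
            if values.size == 0:
                row.update({k: np.nan for k in (
                    "mean_hz", "sd_hz", "p1_hz", "p99_hz",
                    "mean_mm", "sd_mm", "p1_mm", "p99_mm")})
                row["missing"] = True
            else:
                dist = offres_to_distortion(values, seq)
                p1h, p99h = np.percentile(values, [1.0, 99.0])
                p1d, p99d = np.percentile(dist, [1.0, 99.0])
                row.update(
                    mean_hz=float(values.mean()), sd_hz=float(values.std()),
                    p1_hz=float(p1h), p99_hz=float(p99h),
                    mean_mm=float(dist.mean()), sd_mm=float(dist.std()),
                    p1_mm=float(p1d), p99_mm=float(p99d), missing=False,
                )
            rows.append(row)
    return pd.DataFrame(rows)
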