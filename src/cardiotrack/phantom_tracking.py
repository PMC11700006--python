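"""Image-based tracking of the phantom's spherical target.

The target's centre of gravity is detected per frame with a circular
Hough transform on spatially upsampled frames (linear interpolation),
the image-derived trace is temporally aligned to the phantom-reported
reference by cross-correlation (the imaging latency), and the agreement
is scored with per-axis and in-plane RMSE.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .containers import CineSeries, MotionTrace, TrackingResult
from .errors import DegenerateInputError, InsufficientDataError, InvalidParameterError

__all__ = [
    "track_sphere",
    "estimate_latency",
    "score_rmse",
    "track_and_score",
]


def _ring_kernels(shape, radius_px):
    """Radial-vote ring kernels, centred at the origin for FFT use.

    Returns ``(k_row, k_col)``: an anti-aliased annulus of ~1 px width
    multiplied by the outward unit vector and normalized by the ring
    mass.  Correlating the (negated) image gradient with these kernels
    accumulates the inward radial gradient component along the circle —
    straight edges crossing the ring cancel, only contours curving
    around the candidate centre vote coherently."""
    h, w = shape
    rr = np.arange(h, dtype=float)
    cc = np.arange(w, dtype=float)
    rr = np.where(rr <= h / 2, rr, rr - h)[:, None]
    cc = np.where(cc <= w / 2, cc, cc - w)[None, :]
    d = np.sqrt(rr**2 + cc**2)
    ring = np.clip(1.0 - np.abs(d - radius_px), 0.0, 1.0)
    s = ring.sum()
    if s > 0:
        ring = ring / s
    with np.errstate(invalid="ignore", divide="ignore"):
        ur = np.where(d > 0, rr / d, 0.0)
        uc = np.where(d > 0, cc / d, 0.0)
    return ring * ur, ring * uc


def _parabolic_offset(y_minus, y_0, y_plus):
    denom = y_minus - 2.0 * y_0 + y_plus
    if abs(denom) < 1e-12:
        return 0.0
    return float(np.clip(0.5 * (y_minus - y_plus) / denom, -1.0, 1.0))


def track_sphere(
    cine: CineSeries,
    radius_range_mm: tuple[float, float] = (12.0, 18.0),
    upsample: int = 5,
    radius_step_px: float = 0.25,
    min_score: float = 0.35,
) -> MotionTrace:
    """Detect the sphere centre in every frame via circular Hough voting.

    Each frame is linearly interpolated onto an ``upsample``-times finer
    grid; the Hough accumulator is the mean gradient magnitude along a
    circle of each candidate radius (swept over ``radius_range_mm`` in
    ``radius_step_px`` reconstructed-pixel steps), evaluated at every
    candidate centre by FFT ring correlation.  The global accumulator
    peak gives the centre; ties are broken by the larger vote, then the
    smaller radius (the sweep ascends, ``argmax`` keeps the first).
    Sub-pixel localisation uses parabolic interpolation of the peak.

    Frames whose normalized peak vote falls below ``min_score`` (no
    circle of a bracketed radius present) are flagged invalid with NaN
    positions rather than raising.
    """
    if upsample < 1:
        raise InvalidParameterError("upsample must be >= 1")
    lo_mm, hi_mm = radius_range_mm
    if not 0 < lo_mm < hi_mm:
        raise InvalidParameterError("radius_range_mm must be an increasing positive pair")

    px = cine.pixel_mm[0]
    up_px = px / upsample
    radii_px = np.arange(lo_mm / px, hi_mm / px + 1e-9, radius_step_px)
    radii_up = radii_px * upsample

    up_shape = (cine.shape[0] * upsample, cine.shape[1] * upsample)
    ring_ffts = []
    for r in radii_up:
        kr, kc = _ring_kernels(up_shape, r)
        ring_ffts.append((np.fft.rfft2(kr), np.fft.rfft2(kc)))

    n = cine.n_frames
    pos = np.full((n, 2), np.nan)
    valid = np.zeros(n, dtype=bool)
    for k in range(n):
        frame = ndimage.zoom(cine.frames[k], upsample, order=1, grid_mode=True,
                             mode="nearest")
        g0, g1 = np.gradient(frame)
        g0_fft = np.fft.rfft2(g0)
        g1_fft = np.fft.rfft2(g1)
        best = (-np.inf, None, None)
        for i, (kr_fft, kc_fft) in enumerate(ring_ffts):
            # inward radial gradient of a bright disk votes positive
            acc = -(np.fft.irfft2(g0_fft * np.conj(kr_fft), s=up_shape)
                    + np.fft.irfft2(g1_fft * np.conj(kc_fft), s=up_shape))
            idx = np.unravel_index(np.argmax(acc), acc.shape)
            if acc[idx] > best[0]:
                best = (acc[idx], idx, (i, acc))
        peak, idx, (i_best, acc) = best
        span = np.percentile(frame, 99) - np.percentile(frame, 1)
        score = peak * upsample / max(span, 1e-12)
        if score < min_score:
            continue
        # sub-pixel peak: accumulator centroid over a +-2 recon-px window
        # (averages out the gradient staircase of the linear upsampling)
        r0, c0 = idx
        w = 2 * upsample
        rlo, rhi = max(r0 - w, 0), min(r0 + w + 1, up_shape[0])
        clo, chi = max(c0 - w, 0), min(c0 + w + 1, up_shape[1])
        win = acc[rlo:rhi, clo:chi] - acc[rlo:rhi, clo:chi].min()
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        mass = win.sum()
        if mass > 0:
            pos_up = np.array([(win * rr).sum(), (win * cc).sum()]) / mass
        else:
            pos_up = np.array([float(r0), float(c0)])
        # grid_mode zoom maps original index x to upsample*x + (upsample-1)/2
        pos_orig = (pos_up - (upsample - 1) / 2.0) / upsample
        pos[k] = cine.px_to_mm(pos_orig)
        valid[k] = True

    if not np.any(valid):
        warnings.warn("no frame produced a detection above threshold")
    return MotionTrace(cine.times_ms, pos, cine.axes, source="image_derived",
                       valid=valid)


def estimate_latency(
    measured: MotionTrace,
    reference: MotionTrace,
    max_lag_ms: float = 1000.0,
    grid_dt_ms: float | None = None,
) -> float:
    """Time offset (ms) by which ``measured`` lags ``reference``.

    Both traces are linearly resampled to a common fine grid and the
    normalized cross-correlation is maximized over integer lags, with
    parabolic interpolation of the correlation peak for sub-sample
    resolution.  Correlation uses the axis of largest variance shared by
    both traces (the dominant motion axis).
    """
    axis = _dominant_shared_axis(measured, reference)
    tm, xm = _valid_series(measured, axis)
    tr, xr = _valid_series(reference, axis)
    if np.std(xm) < 1e-12 or np.std(xr) < 1e-12:
        raise DegenerateInputError("cannot correlate a constant trace")

    if grid_dt_ms is None:
        grid_dt_ms = max(min(np.median(np.diff(tm)), np.median(np.diff(tr))) / 4.0, 1.0)
    lo = max(tm.min() - max_lag_ms, tr.min())
    hi = min(tm.max() + max_lag_ms, tr.max())
    if hi - lo <= 2 * grid_dt_ms:
        raise InsufficientDataError("traces do not overlap in time")
    grid = np.arange(lo, hi + grid_dt_ms / 2, grid_dt_ms)
    a = np.interp(grid, tm, xm)
    b = np.interp(grid, tr, xr)
    a = a - a.mean()
    b = b - b.mean()

    max_lag = int(round(max_lag_ms / grid_dt_ms))
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(lags.size)
    for j, lag in enumerate(lags):
        if lag >= 0:
            x, y = a[lag:], b[: b.size - lag]
        else:
            x, y = a[:lag], b[-lag:]
        denom = np.sqrt(np.sum(x * x) * np.sum(y * y))
        corr[j] = np.sum(x * y) / denom if denom > 0 else -np.inf
    j0 = int(np.argmax(corr))
    offset = 0.0
    if 0 < j0 < lags.size - 1 and np.isfinite(corr[j0 - 1]) and np.isfinite(corr[j0 + 1]):
        offset = _parabolic_offset(corr[j0 - 1], corr[j0], corr[j0 + 1])
    return float((lags[j0] + offset) * grid_dt_ms)


def _dominant_shared_axis(a: MotionTrace, b: MotionTrace) -> str:
    shared = [ax for ax in a.axes if ax in b.axes]
    if not shared:
        raise InvalidParameterError(f"traces share no axis: {a.axes} vs {b.axes}")
    variances = [np.nanvar(a.axis(ax)[a.valid]) for ax in shared]
    return shared[int(np.argmax(variances))]


def _valid_series(trace: MotionTrace, axis: str):
    m = trace.valid
    return trace.t_ms[m], trace.axis(axis)[m]


def score_rmse(
    measured: MotionTrace,
    reference: MotionTrace,
    latency_ms: float = 0.0,
) -> dict:
    """Per-axis (and in-plane 2D) RMSE of ``measured`` vs ``reference``.

    The measured trace is shifted back by the latency, the reference is
    linearly resampled to the corrected measured timestamps, and the
    root-mean-squared point-wise difference is taken per shared axis.
    When both in-plane axes are shared, the Euclidean ``"2D"`` RMSE is
    also reported.
    """
    shared = [ax for ax in measured.axes if ax in reference.axes]
    if not shared:
        raise InvalidParameterError("traces share no axis")
    t_corr = measured.t_ms[measured.valid] - latency_ms
    keep = (t_corr >= reference.t_ms.min()) & (t_corr <= reference.t_ms.max())
    if np.count_nonzero(keep) < 2:
        raise InsufficientDataError("fewer than 2 overlapping samples")
    out = {}
    sq_2d = np.zeros(np.count_nonzero(keep))
    for ax in shared:
        meas = measured.axis(ax)[measured.valid][keep]
        ref = np.interp(t_corr[keep], reference.t_ms, reference.axis(ax))
        diff = meas - ref
        out[ax] = float(np.sqrt(np.mean(diff**2)))
        if len(shared) >= 2:
            sq_2d += diff**2
    if len(shared) >= 2:
        out["2D"] = float(np.sqrt(np.mean(sq_2d)))
    return out


def track_and_score(
    cine: CineSeries,
    reference: MotionTrace,
    radius_range_mm: tuple[float, float] = (12.0, 18.0),
    upsample: int = 5,
) -> TrackingResult:
    """Full phantom chain: Hough tracking, latency alignment, RMSE."""
    trace = track_sphere(cine, radius_range_mm, upsample)
    latency = estimate_latency(trace, reference)
    rmse = score_rmse(trace, reference, latency)
    return TrackingResult(trace=trace, latency_ms=latency, rmse_mm=rmse,
                          upsample_factor=upsample)
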