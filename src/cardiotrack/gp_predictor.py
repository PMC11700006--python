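"""Real-time landmark-motion prediction with Gaussian processes.

A subject-specific GP regressor maps cheap per-frame navigator features
(the two normalized image projections, concatenated and reduced by PCA)
to landmark positions.  It is trained on the first half of a cine series
using registration-derived landmark positions as ground truth and then
predicts positions for the remaining frames from single projection sets,
at a per-frame cost compatible with real-time use.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.preprocessing import StandardScaler

from .containers import CineSeries, LandmarkTrack, MotionTrace
from .errors import ContractError, InsufficientDataError, InvalidParameterError
from .metrics import rmsd
from .synthdata import navigator_projections

__all__ = [
    "TrainTestSplit",
    "GPModel",
    "cine_features",
    "fit_gp",
    "predict",
    "evaluate_prediction",
]


@dataclass(frozen=True)
class TrainTestSplit:
    """Contiguous train-first split of a cine's frame indices."""

    n_frames: int
    train_fraction: float = 0.5

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise InvalidParameterError("train_fraction must be in (0, 1)")
        if self.n_frames < 2:
            raise InvalidParameterError("need at least 2 frames")

    @property
    def train_idx(self) -> np.ndarray:
        return np.arange(int(round(self.n_frames * self.train_fraction)))

    @property
    def test_idx(self) -> np.ndarray:
        return np.arange(int(round(self.n_frames * self.train_fraction)), self.n_frames)


@dataclass
class GPModel:
    """Trained navigator-to-position regressor (one GP per output axis)."""

    scaler: StandardScaler
    reducer: PCA
    gps: list
    axes: tuple[str, ...]
    n_features: int
    trained: bool = True

    def __post_init__(self):
        if self.trained and not self.gps:
            raise InvalidParameterError("a trained model needs at least one GP")


def cine_features(cine: CineSeries) -> np.ndarray:
    """Per-frame navigator feature matrix ``(T, H + W)``.

    Row ``t`` is the concatenation of the two unit-normalized image
    projections of frame ``t``.
    """
    feats = []
    for f in cine.frames:
        p0, p1 = navigator_projections(f)
        feats.append(np.concatenate([p0, p1]))
    return np.asarray(feats)


def fit_gp(
    features: np.ndarray,
    targets: LandmarkTrack | np.ndarray,
    split: TrainTestSplit,
    seed: int = 0,
    variance_keep: float = 0.95,
    n_restarts: int = 3,
    axes: tuple[str, ...] | None = None,
) -> GPModel:
    """Train the GP on the training split of (features, targets).

    Features are standardized and reduced by principal components
    retaining ``variance_keep`` of the variance (both fit on the
    training split only); each output coordinate gets an independent
    RBF + white-noise GP with hyperparameters chosen by maximizing the
    log marginal likelihood with ``n_restarts`` restarts (seeded).
    """
    X = np.asarray(features, dtype=float)
    if isinstance(targets, LandmarkTrack):
        Y = targets.pos_mm
        axes = axes or targets.axes
    else:
        Y = np.atleast_2d(np.asarray(targets, dtype=float))
        if Y.shape[0] != X.shape[0]:
            Y = Y.T
        axes = axes or tuple(f"axis{i}" for i in range(Y.shape[1]))
    if X.shape[0] != Y.shape[0]:
        raise ContractError("features and targets must cover the same frames")
    if not np.all(np.isfinite(X)):
        raise InvalidParameterError("features must be finite")
    tr = split.train_idx
    if tr.size < 20:
        raise InsufficientDataError(f"need >= 20 training frames, got {tr.size}")

    half = X.shape[1] // 2
    for name, block in (("axis-0 projections", X[tr, :half]),
                        ("axis-1 projections", X[tr, half:])):
        if block.size and float(np.max(np.var(block, axis=0))) < 1e-18:
            raise InvalidParameterError(f"degenerate features: {name} have zero variance")

    scaler = StandardScaler().fit(X[tr])
    Xs = scaler.transform(X[tr])
    reducer = PCA(n_components=variance_keep, svd_solver="full").fit(Xs)
    Z = reducer.transform(Xs)

    gps = []
    for j in range(Y.shape[1]):
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e3))
            * RBF(length_scale=1.0, length_scale_bounds=(1e-2, 1e3))
            + WhiteKernel(noise_level=1e-4, noise_level_bounds=(1e-12, 1e1))
        )
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, n_restarts_optimizer=n_restarts,
            random_state=seed,
        )
        gp.fit(Z, Y[tr, j])
        gps.append(gp)
    return GPModel(scaler=scaler, reducer=reducer, gps=gps, axes=tuple(axes),
                   n_features=X.shape[1])


def predict(model: GPModel, features_t: np.ndarray):
    """Posterior mean and SD per axis for one frame (or a batch).

    ``features_t`` is one concatenated projection vector or a ``(T, d)``
    batch.  Returns ``(mean, sd)`` with shape ``(k,)`` for one frame or
    ``(T, k)`` for a batch.
    """
    if not model.trained:
        raise InvalidParameterError("model is not trained")
    X = np.atleast_2d(np.asarray(features_t, dtype=float))
    if X.shape[1] != model.n_features:
        raise ContractError(
            f"feature length {X.shape[1]} != expected {model.n_features}"
        )
    Z = model.reducer.transform(model.scaler.transform(X))
    means, sds = [], []
    for gp in model.gps:
        m, s = gp.predict(Z, return_std=True)
        means.append(m)
        sds.append(s)
    mean = np.stack(means, axis=1)
    sd = np.stack(sds, axis=1)
    if np.asarray(features_t).ndim == 1:
        return mean[0], sd[0]
    return mean, sd


def predict_trace(model: GPModel, features: np.ndarray, t_ms: np.ndarray) -> MotionTrace:
    """Convenience wrapper returning predictions as a MotionTrace."""
    mean, _ = predict(model, features)
    return MotionTrace(t_ms, mean, model.axes, source="gp")


def evaluate_prediction(model_out: MotionTrace, reference: MotionTrace) -> dict:
    """Per-frame in-plane Euclidean deviation and its RMS.

    Both traces must cover the same frames.  Returns ``{"pwd_2d":
    series, "rmsd_2d": scalar}``.
    """
    if len(model_out) != len(reference):
        raise ContractError("traces must cover the same frames")
    shared = [ax for ax in model_out.axes if ax in reference.axes][:2]
    diffs = np.stack(
        [model_out.axis(ax) - reference.axis(ax) for ax in shared], axis=1
    )
    pwd_2d = np.sqrt(np.sum(diffs**2, axis=1))
    return {"pwd_2d": pwd_2d, "rmsd_2d": rmsd(pwd_2d)}


def timed_predict(model: GPModel, features: np.ndarray):
    """Batch prediction with mean per-frame wall time (seconds)."""
    X = np.atleast_2d(features)
    t0 = time.perf_counter()
    out = predict(model, X)
    per_frame = (time.perf_counter() - t0) / X.shape[0]
    return out, per_frame
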