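"""Feature scaling, wavelet framing and the time-series → supervised transform.

Four per-channel scaling schemes are supported: *standard* (zero mean, unit
variance), *robust* (median/IQR), *minmax* (to [0, 1]) and *normalizer*
(each sample row divided by its Euclidean norm; stateless).  SD follows the
population (1/N) convention throughout the package.

The supervised transform turns a univariate series into sliding windows of
``lag`` past samples paired with the next sample as target — the standard
framing for one-step-ahead forecasting.  Wavelet framing decomposes a
series (or fixed-length frames of it) with a discrete wavelet transform,
db4 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .signal_io import SignalFrame

SCALER_KINDS = ("standard", "robust", "minmax", "normalizer")

#: default number of past samples feeding the forecaster
DEFAULT_LAG = 10

#: default non-overlapping frame length for wavelet analysis
DEFAULT_FRAME_LENGTH = 256


@dataclass
class ScalerParams:
    """Fitted per-channel location/scale statistics for one scaling scheme.

    ``center`` and ``scale`` are per-channel arrays (empty for the stateless
    normalizer).  A constant channel yields scale 0, which `transform`
    maps to all-zero output rather than dividing by zero.
    """

    kind: str
    center: np.ndarray = field(default_factory=lambda: np.array([]))
    scale: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_channels(self) -> int:
        return self.center.shape[0]


@dataclass
class SupervisedDataset:
    """Lagged design matrix and one-step-ahead targets from one channel.

    Row ``i`` of ``X`` is ``series[i : i + lag]`` and ``y[i]`` is
    ``series[i + lag]``, so ``X[:, 0]`` followed by the last ``lag`` values
    of the series reconstructs the input exactly.
    """

    X: np.ndarray
    y: np.ndarray
    lag: int
    source_channel: str = ""

    def reconstruct_series(self) -> np.ndarray:
        """Invert the supervised transform back to the original series."""
        return np.concatenate([self.X[0], self.y])


def fit_scaler(kind: str, frame: SignalFrame) -> ScalerParams:
    """Fit per-channel scaling statistics on a frame.

    standard → mean and population SD; robust → median and IQR (Q3 − Q1,
    linear-interpolation quantiles); minmax → min and range; normalizer →
    stateless (no statistics).
    """
    if kind not in SCALER_KINDS:
        raise ValueError(f"unknown scaler kind {kind!r}")
    if frame.n_samples == 0:
        raise ValueError("cannot fit a scaler on an empty frame")
    data = frame.data
    if kind == "standard":
        return ScalerParams("standard", data.mean(axis=0), data.std(axis=0))
    if kind == "robust":
        q1, med, q3 = np.percentile(data, [25, 50, 75], axis=0)
        return ScalerParams("robust", med, q3 - q1)
    if kind == "minmax":
        lo, hi = data.min(axis=0), data.max(axis=0)
        return ScalerParams("minmax", lo, hi - lo)
    return ScalerParams("normalizer")


def transform(params: ScalerParams, frame: SignalFrame) -> SignalFrame:
    """Apply fitted scaling to a frame, returning a new frame.

    Channels whose fitted scale is 0 (constant channels) map to 0.  The
    normalizer divides each sample row by its Euclidean norm (zero rows
    stay zero).
    """
    data = frame.data
    if params.kind == "normalizer":
        norms = np.linalg.norm(data, axis=1, keepdims=True)
        norms[norms == 0.0] = 1.0
        return SignalFrame(data / norms, list(frame.channel_names))
    if params.n_channels != frame.n_channels:
        raise ValueError(
            f"scaler fitted on {params.n_channels} channels, frame has {frame.n_channels}"
        )
    scale = np.where(params.scale == 0.0, 1.0, params.scale)
    out = (data - params.center) / scale
    out[:, params.scale == 0.0] = 0.0
    return SignalFrame(out, list(frame.channel_names))


def to_supervised(series, lag: int = DEFAULT_LAG, source_channel: str = "") -> SupervisedDataset:
    """Sliding-window supervised transform: ``lag`` past samples → next sample."""
    series = np.asarray(series, dtype=float).ravel()
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if series.size <= lag:
        raise ValueError(
            f"series of length {series.size} too short; need at least lag+1 = {lag + 1}"
        )
    windows = np.lib.stride_tricks.sliding_window_view(series, lag + 1)
    return SupervisedDataset(
        X=windows[:, :lag].copy(),
        y=windows[:, lag].copy(),
        lag=lag,
        source_channel=source_channel,
    )


def dwt_frames(series, wavelet: str = "db4", level: int = 4, mode: str = "symmetric"):
    """Multilevel discrete wavelet decomposition of a 1-D series.

    Returns the coefficient bands ordered coarse → fine: the level-``level``
    approximation band first, then detail bands down to level 1.  ``mode``
    is the signal-extension mode; under ``periodization`` the orthogonal
    db4 transform conserves energy exactly.
    """
    series = np.asarray(series, dtype=float).ravel()
    if level < 1:
        raise ValueError("level must be >= 1")
    max_level = pywt.dwt_max_level(series.size, pywt.Wavelet(wavelet).dec_len)
    if level > max_level:
        raise ValueError(
            f"level {level} too deep for series of length {series.size} "
            f"with {wavelet} (max usable level {max_level})"
        )
    return pywt.wavedec(series, wavelet, mode=mode, level=level)


def idwt_frames(bands, wavelet: str = "db4", mode: str = "symmetric") -> np.ndarray:
    """Inverse of :func:`dwt_frames` (perfect reconstruction)."""
    return pywt.waverec(list(bands), wavelet, mode=mode)


def frame_series(series, frame_length: int = DEFAULT_FRAME_LENGTH) -> np.ndarray:
    """Cut a series into non-overlapping frames; the trailing partial frame is dropped."""
    series = np.asarray(series, dtype=float).ravel()
    if frame_length < 1:
        raise ValueError("frame_length must be >= 1")
    n_frames = series.size // frame_length
    if n_frames == 0:
        raise ValueError(
            f"series of length {series.size} shorter than one frame ({frame_length})"
        )
    return series[: n_frames * frame_length].reshape(n_frames, frame_length)
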