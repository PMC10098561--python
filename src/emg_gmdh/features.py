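"""Time-domain EMG window features.

All features operate on a single window of samples X_1..X_N (1-based in the
formulas below) and are the classical surface-EMG time-domain set:

- IEMG  = Σ|X_i|                      integrated absolute value
- MAV   = IEMG / N                    mean absolute value
- MAV1  = (1/N) Σ w_i |X_i|           centre-weighted MAV, w_i = 1 for
          0.25N ≤ i ≤ 0.75N (inclusive, unrounded bounds), else 0.5
- RMS   = sqrt((1/N) Σ X_i²)
- AAC   = (1/N) Σ_{i<N} |X_{i+1} − X_i|   (divisor N by convention here)
- ZC    = #{i < N : X_i·X_{i+1} < 0 and |X_i − X_{i+1}| ≥ thr}
- SSC   = #{1 < i < N : (X_i − X_{i−1})(X_i − X_{i+1}) ≥ thr}
- WAMP  = #{i < N : |X_i − X_{i+1}| ≥ thr}   Willison amplitude
- WL    = Σ_{i<N} |X_{i+1} − X_i|     waveform length (= N·AAC)
- SD    = population standard deviation (1/N)

Counts (ZC/SSC/WAMP) are returned as floats for uniform table handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .signal_io import SignalFrame

FEATURE_NAMES = ("IEMG", "MAV", "MAV1", "RMS", "AAC", "ZC", "SSC", "WAMP", "WL", "SD")


def _window(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("feature window must be non-empty")
    return x


def iemg(window) -> float:
    """Integrated EMG: sum of absolute values."""
    return float(np.sum(np.abs(_window(window))))


def mav(window) -> float:
    """Mean absolute value."""
    x = _window(window)
    return float(np.sum(np.abs(x)) / x.size)


def mav1(window) -> float:
    """Modified MAV type 1: unit weight in the central half, 0.5 outside."""
    x = _window(window)
    n = x.size
    if n < 2:
        raise ValueError("MAV1 needs a window of at least 2 samples")
    i = np.arange(1, n + 1)  # 1-based sample index, bounds compared unrounded
    w = np.where((i >= 0.25 * n) & (i <= 0.75 * n), 1.0, 0.5)
    return float(np.sum(w * np.abs(x)) / n)


def rms(window) -> float:
    """Root mean square amplitude."""
    x = _window(window)
    return float(np.sqrt(np.sum(x**2) / x.size))


def aac(window) -> float:
    """Average amplitude change: waveform length divided by N."""
    x = _window(window)
    return float(np.sum(np.abs(np.diff(x))) / x.size)


def zc(window, threshold: float = 0.0) -> float:
    """Zero crossings: sign changes whose step also clears the threshold."""
    x = _window(window)
    sign_change = x[:-1] * x[1:] < 0.0
    big_step = np.abs(x[:-1] - x[1:]) >= threshold
    return float(np.count_nonzero(sign_change & big_step))


def ssc(window, threshold: float = 0.0) -> float:
    """Slope sign changes: interior samples that are local extrema.

    Counts interior i with (X_i − X_{i−1})(X_i − X_{i+1}) ≥ threshold.
    Windows shorter than 3 samples have no interior point and count 0.
    """
    x = _window(window)
    if x.size < 3:
        return 0.0
    left = x[1:-1] - x[:-2]
    right = x[1:-1] - x[2:]
    return float(np.count_nonzero(left * right >= threshold))


def wamp(window, threshold: float = 0.0) -> float:
    """Willison amplitude: consecutive steps at least as large as the threshold."""
    x = _window(window)
    return float(np.count_nonzero(np.abs(x[:-1] - x[1:]) >= threshold))


def wl(window) -> float:
    """Waveform length: total variation of the window."""
    x = _window(window)
    return float(np.sum(np.abs(np.diff(x))))


def sd(window) -> float:
    """Population (1/N) standard deviation."""
    x = _window(window)
    return float(np.std(x))


_SIMPLE: dict[str, Callable] = {
    "IEMG": iemg,
    "MAV": mav,
    "MAV1": mav1,
    "RMS": rms,
    "AAC": aac,
    "WL": wl,
    "SD": sd,
}


@dataclass
class FeatureConfig:
    """Windowing and threshold settings for feature extraction.

    ``wamp_threshold=None`` selects an adaptive threshold of 0.05 × the
    window's RMS, a common choice when sensor units are unknown; ZC and SSC
    default to threshold 0.
    """

    window_length: int = 256
    window_step: int = 256
    zc_threshold: float = 0.0
    wamp_threshold: float | None = None
    ssc_threshold: float = 0.0
    feature_set: Sequence[str] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if self.window_step < 1:
            raise ValueError("window_step must be >= 1")
        for thr in (self.zc_threshold, self.ssc_threshold):
            if thr < 0:
                raise ValueError("thresholds must be >= 0")
        if self.wamp_threshold is not None and self.wamp_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        unknown = set(self.feature_set) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features: {sorted(unknown)}")
        self.feature_set = tuple(self.feature_set)


@dataclass
class FeatureVector:
    """Ordered (channel, feature, value) triples for one analysis window."""

    window_start: int
    values: list[tuple[str, str, float]] = field(default_factory=list)

    def value(self, channel: str, feature: str) -> float:
        for ch, name, val in self.values:
            if ch == channel and name == feature:
                return val
        raise KeyError((channel, feature))


def compute_feature(name: str, window, config: FeatureConfig) -> float:
    """Evaluate one named feature on one window under the config thresholds."""
    if name in _SIMPLE:
        return _SIMPLE[name](window)
    if name == "ZC":
        return zc(window, config.zc_threshold)
    if name == "SSC":
        return ssc(window, config.ssc_threshold)
    if name == "WAMP":
        thr = config.wamp_threshold
        if thr is None:
            thr = 0.05 * rms(window)
        return wamp(window, thr)
    raise ValueError(f"unknown feature {name!r}")


def extract_features(frame: SignalFrame, config: FeatureConfig) -> list[FeatureVector]:
    """Per-window, per-channel feature extraction over a multichannel frame.

    Windows start at 0, step, 2·step, …; a trailing window that does not
    fill ``window_length`` samples is dropped.  Values appear channel-major
    in ``feature_set`` order.
    """
    n = frame.n_samples
    if n < config.window_length:
        raise ValueError(
            f"frame of {n} samples shorter than one window ({config.window_length})"
        )
    vectors = []
    for start in range(0, n - config.window_length + 1, config.window_step):
        fv = FeatureVector(window_start=start)
        block = frame.data[start : start + config.window_length]
        for ch_idx, ch_name in enumerate(frame.channel_names):
            window = block[:, ch_idx]
            for name in config.feature_set:
                fv.values.append((ch_name, name, compute_feature(name, window, config)))
        vectors.append(fv)
    return vectors


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Long-format table with columns window_start, channel, feature, value."""
    rows = [
        (fv.window_start, ch, name, val)
        for fv in vectors
        for ch, name, val in fv.values
    ]
    return pd.DataFrame(rows, columns=["window_start", "channel", "feature", "value"])


def write_features_csv(vectors: list[FeatureVector], path) -> None:
    features_to_frame(vectors).to_csv(path, index=False)
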