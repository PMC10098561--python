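"""Seeded synthetic EMG-like signals and regression fixtures.

Surface EMG at rest looks like band-limited, zero-mean stochastic noise;
muscle activity shows up as amplitude bursts.  The generator emulates that
with amplitude-modulated autoregressive (AR) noise: a stationary AR process
shaped to a broad spectral peak, multiplied by an envelope that is 1 at
baseline and rises to ``burst_amplitude`` inside burst windows placed by a
seeded Bernoulli point process.  Two named regimes mirror the qualitative
contrast between ordinary ("normal") activity and violent ("aggressive")
activity: the aggressive regime fires more bursts with a much larger gain,
so its peak amplitudes are systematically higher.

Everything here is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .signal_io import SignalFrame

#: per-regime (burst_rate per 1,000 samples, burst_amplitude) defaults
REGIME_DEFAULTS = {
    "normal": {"burst_rate": 1.0, "burst_amplitude": 3.0},
    "aggressive": {"burst_rate": 4.0, "burst_amplitude": 10.0},
}

#: AR(2) shaping giving a broad mid-band spectral peak
DEFAULT_AR_COEFFS = (0.9, -0.5)


def _check_stationary(coeffs: Sequence[float]) -> np.ndarray:
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size:
        # companion roots of z^p - a1 z^(p-1) - ... - ap must lie inside the unit circle
        roots = np.roots(np.concatenate(([1.0], -coeffs)))
        if np.any(np.abs(roots) >= 1.0 - 1e-12):
            raise ValueError(f"AR coefficients {coeffs.tolist()} are not stationary")
    return coeffs


def _ar_stationary_sd(coeffs: np.ndarray, n_psi: int = 4096) -> float:
    """SD of the stationary AR process driven by unit-variance noise.

    Computed from the MA(inf) representation: var = sum of squared impulse
    response weights, truncated where the geometric tail is negligible.
    """
    if coeffs.size == 0:
        return 1.0
    impulse = np.zeros(n_psi)
    impulse[0] = 1.0
    psi = lfilter([1.0], np.concatenate(([1.0], -coeffs)), impulse)
    return float(np.sqrt(np.sum(psi**2)))


@dataclass
class EmgSimConfig:
    """Parameters of the synthetic EMG generator.

    ``burst_rate`` (expected burst starts per 1,000 samples) and
    ``burst_amplitude`` (envelope gain inside a burst) default from the
    regime; explicit values override.  ``baseline_sd`` is the stationary
    amplitude SD outside bursts, in the same arbitrary units as the output.
    """

    n_channels: int = 8
    n_samples: int = 10_000
    regime: str = "normal"
    baseline_sd: float = 1.0
    burst_rate: float | None = None
    burst_amplitude: float | None = None
    burst_duration_mean: float = 100.0
    ar_coeffs: Sequence[float] = DEFAULT_AR_COEFFS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIME_DEFAULTS:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.burst_rate is None:
            self.burst_rate = REGIME_DEFAULTS[self.regime]["burst_rate"]
        if self.burst_amplitude is None:
            self.burst_amplitude = REGIME_DEFAULTS[self.regime]["burst_amplitude"]
        if self.n_samples < 1 or self.n_channels < 1:
            raise ValueError("n_samples and n_channels must be >= 1")
        if self.baseline_sd <= 0:
            raise ValueError("baseline_sd must be > 0")
        if self.burst_amplitude < 1:
            raise ValueError("burst_amplitude must be >= 1")
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be >= 0")
        if self.burst_duration_mean < 1:
            raise ValueError("burst_duration_mean must be >= 1")
        self.ar_coeffs = tuple(float(c) for c in self.ar_coeffs)
        _check_stationary(self.ar_coeffs)


def _burst_envelope(config: EmgSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Envelope gain per sample: 1 at baseline, burst_amplitude inside bursts.

    Burst starts follow a Bernoulli process at rate burst_rate/1,000 per
    sample; durations are exponential with the configured mean.  Overlapping
    bursts take the maximum envelope, which here is simply the burst gain.
    """
    n = config.n_samples
    envelope = np.ones(n)
    p_start = config.burst_rate / 1000.0
    starts = np.flatnonzero(rng.random(n) < p_start)
    durations = np.maximum(1, np.round(rng.exponential(config.burst_duration_mean, size=starts.size))).astype(int)
    for start, dur in zip(starts, durations):
        envelope[start : start + dur] = config.burst_amplitude
    return envelope


def simulate_emg(config: EmgSimConfig) -> SignalFrame:
    """Generate a seeded multichannel EMG-like signal frame.

    Each channel is an independent AR realization rescaled so its baseline
    stationary SD equals ``baseline_sd``, multiplied by a burst envelope
    shared across channels (a physical action recruits several muscles at
    once).  Identical config and seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    coeffs = np.asarray(config.ar_coeffs, dtype=float)
    unit_sd = _ar_stationary_sd(coeffs)
    envelope = _burst_envelope(config, rng)
    burn_in = 10 * max(1, coeffs.size)
    data = np.empty((config.n_samples, config.n_channels))
    for ch in range(config.n_channels):
        noise = rng.standard_normal(config.n_samples + burn_in)
        series = lfilter([1.0], np.concatenate(([1.0], -coeffs)), noise)[burn_in:]
        data[:, ch] = series * (config.baseline_sd / unit_sd) * envelope
    return SignalFrame(data)


def simulate_ar_series(
    coeffs: Sequence[float], n: int, noise_sd: float, seed: int
) -> np.ndarray:
    """Seeded AR(p) realization of length ``n`` with 10·p burn-in discarded."""
    coeffs = _check_stationary(coeffs)
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    burn_in = 10 * max(1, coeffs.size)
    noise = rng.standard_normal(n + burn_in) * noise_sd
    series = lfilter([1.0], np.concatenate(([1.0], -coeffs)), noise)
    return series[burn_in:]


def simulate_polynomial_dataset(
    ref_function: str,
    weights: Sequence[float],
    n: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two uniform(−1, 1) columns and targets = polynomial basis · weights + noise.

    The basis is the partial-polynomial form named by ``ref_function``
    (see :func:`emg_gmdh.gmdh_core.polynomial_terms`); the weight vector
    must match its size.
    """
    from .gmdh_core import basis_size, polynomial_terms

    weights = np.asarray(weights, dtype=float)
    expected = basis_size(ref_function)
    if weights.size != expected:
        raise ValueError(
            f"{ref_function!r} basis has {expected} terms, got {weights.size} weights"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1.0, 1.0, size=(n, 2))
    basis = polynomial_terms(ref_function, X[:, 0], X[:, 1])
    y = basis @ weights + rng.standard_normal(n) * noise_sd
    return X, y


def simulate_regime_pair(seed: int, **overrides) -> tuple[SignalFrame, SignalFrame]:
    """Convenience: (normal, aggressive) frames from the same seed family."""
    normal = simulate_emg(EmgSimConfig(regime="normal", seed=seed, **overrides))
    aggressive = simulate_emg(EmgSimConfig(regime="aggressive", seed=seed, **overrides))
    return normal, aggressive


def replace_config(config: EmgSimConfig, **changes) -> EmgSimConfig:
    """Functional update of a config (re-runs validation)."""
    return replace(config, **changes)
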