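"""Synthetic nonstationary multichannel signals with regime-switching labels.

The generator emulates the kind of per-sample-labelled physiological recording
(EEG, wearable inertial sensors) the classifier is built for: a hidden class
state switches slowly — dwell times are geometric with a configurable mean —
and each state drives every channel with a distinct quasi-periodic AR(2)
regime (distinct dominant frequency per class and channel).  Because the
discriminative information is the oscillatory regime rather than any single
sample, temporal context spanning several windows is genuinely informative,
which is the property the network's concatenation sublayers exploit.

Observation noise is white Gaussian, scaled per channel to a linear
signal-to-noise ratio.  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .data_prep import TimeSeriesRecord

__all__ = ["SynthSpec", "generate", "class_frequencies"]

# regime transitions are cross-faded over this many samples to avoid
# discontinuities at the switch points
_SMOOTH_SAMPLES = 5
_POLE_RADIUS = 0.95


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters.

    ``mean_dwell`` is the expected number of samples between latent-state
    switches (geometric dwell distribution); ``snr`` the linear power ratio
    of the AR signal to the additive Gaussian noise.  Defaults emulate a
    14-channel, two-state recording of ~15 k samples with dwell times long
    relative to typical window lengths.
    """

    n_channels: int = 14
    n_samples: int = 15_000
    n_classes: int = 2
    mean_dwell: float = 300.0
    snr: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_samples < 1:
            raise ValueError("need at least one channel and one sample")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.mean_dwell < 1:
            raise ValueError("mean_dwell must be >= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def class_frequencies(spec: SynthSpec) -> np.ndarray:
    """Dominant normalized frequency of each (class, channel) regime.

    Classes are spread over (0.05, 0.35) cycles/sample with a small per-channel
    offset; returned as a ``(K, C)`` matrix.  Exposed so oracle feature
    extractors (e.g. bandpower classifiers) can target the right bands.
    """
    K, C = spec.n_classes, spec.n_channels
    base = 0.05 + 0.30 * np.arange(K) / (K - 1)
    offset = 0.02 * (np.arange(C) / max(C - 1, 1) - 0.5)
    return base[:, None] + offset[None, :]


def _latent_states(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """K-state Markov chain with geometric dwell of mean ``mean_dwell``.

    From state k the chain stays with probability ``1 - 1/mean_dwell`` and
    otherwise jumps uniformly to one of the other K-1 states, so the
    stationary distribution is uniform.
    """
    N, K = spec.n_samples, spec.n_classes
    p_switch = 1.0 / spec.mean_dwell
    labels = np.empty(N, dtype=np.int64)
    pos = 0
    state = int(rng.integers(K))
    while pos < N:
        dwell = int(rng.geometric(p_switch)) if p_switch < 1.0 else 1
        end = min(pos + dwell, N)
        labels[pos:end] = state
        pos = end
        # jump uniformly among the other states
        step = int(rng.integers(1, K))
        state = (state + step) % K
    return labels


def generate(spec: SynthSpec) -> TimeSeriesRecord:
    """Draw one labelled record from the regime-switching model.

    Per channel the signal follows ``x_t = phi1_t x_{t-1} + phi2_t x_{t-2} + e_t``
    with unit-variance Gaussian innovations, where the AR(2) coefficients
    place a resonance (pole radius 0.95) at the active class's dominant
    frequency; coefficients are cross-faded over 5 samples around each switch.
    White Gaussian noise with per-channel variance ``var(signal)/snr`` is
    added on top.  The per-sample label is the latent state itself.
    """
    rng = np.random.default_rng(spec.seed)
    N, C, K = spec.n_samples, spec.n_channels, spec.n_classes
    labels = _latent_states(spec, rng)

    freqs = class_frequencies(spec)  # (K, C)
    theta = 2.0 * np.pi * freqs
    phi1_k = 2.0 * _POLE_RADIUS * np.cos(theta)  # (K, C)
    phi2_k = np.full_like(phi1_k, -_POLE_RADIUS**2)

    onehot = np.zeros((N, K))
    onehot[np.arange(N), labels] = 1.0
    weights = uniform_filter1d(onehot, size=_SMOOTH_SAMPLES, axis=0, mode="nearest")
    weights /= weights.sum(axis=1, keepdims=True)
    phi1 = weights @ phi1_k  # (N, C)
    phi2 = weights @ phi2_k

    innov = rng.standard_normal((N, C))
    x = np.zeros((N, C))
    xm1 = np.zeros(C)
    xm2 = np.zeros(C)
    for t in range(N):
        xt = phi1[t] * xm1 + phi2[t] * xm2 + innov[t]
        x[t] = xt
        xm2 = xm1
        xm1 = xt

    sig_var = x.var(axis=0)
    noise = rng.standard_normal((N, C)) * np.sqrt(sig_var / spec.snr)
    return TimeSeriesRecord(x + noise, labels, K)
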