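"""Synthetic signal generators used to validate the entropy estimators.

Covers the MIX(p) model (a sinusoid with a fraction ``p`` of samples replaced
by uniform noise on [-3, 3]), white Gaussian noise, 1/f (pink) noise, and
SNR-controlled white-noise injection. Every generator is a pure function of
its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MixParams",
    "NoiseSpec",
    "sinusoid",
    "mix_signal",
    "white_gaussian_noise",
    "one_over_f_noise",
    "add_noise_snr",
]


@dataclass(frozen=True)
class MixParams:
    """Parameters of the MIX(p) model.

    ``p`` is the replacement probability: exactly ``round(N * p)`` of the
    ``N = round(f_s * t)`` sinusoid samples are replaced by draws from
    Uniform(noise_low, noise_high). The [-3, 3] default mirrors the 3-sigma
    range of a standard normal.
    """

    p: float = 0.2
    amplitude: float = 2.0
    freq_hz: float = 10.0
    sample_rate_hz: float = 500.0
    duration_s: float = 3.0
    noise_low: float = -3.0
    noise_high: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.freq_hz <= 0 or self.sample_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("freq_hz, sample_rate_hz and duration_s must be positive")
        if self.noise_low >= self.noise_high:
            raise ValueError("noise_low must be < noise_high")

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate_hz * self.duration_s))


@dataclass(frozen=True)
class NoiseSpec:
    """A pure-noise signal request: white Gaussian or 1/f (pink)."""

    kind: str = "wgn"
    length: int = 1500
    seed: int = 0
    snr_db: float | None = None

    def __post_init__(self):
        if self.kind not in ("wgn", "one_over_f"):
            raise ValueError("kind must be 'wgn' or 'one_over_f'")
        if self.length < 2:
            raise ValueError("length must be >= 2")


def sinusoid(params: MixParams) -> np.ndarray:
    """Pure sinusoid ``A sin(2 pi f n / f_s)``, n = 0..N-1."""
    if params.freq_hz >= params.sample_rate_hz / 2:
        raise ValueError(
            f"freq_hz={params.freq_hz} at or above Nyquist "
            f"({params.sample_rate_hz / 2} Hz)"
        )
    n = np.arange(params.n_samples)
    return params.amplitude * np.sin(
        2.0 * np.pi * params.freq_hz * n / params.sample_rate_hz
    )


def mix_signal(params: MixParams) -> np.ndarray:
    """MIX(p) signal: sinusoid with round(N*p) samples replaced by noise.

    Replacement positions are sampled uniformly without replacement;
    replacement values are i.i.d. Uniform(noise_low, noise_high). Complexity
    of the output increases with ``p``.
    """
    x = sinusoid(params)
    n_replace = int(round(params.n_samples * params.p))
    if n_replace == 0:
        return x
    rng = np.random.default_rng(params.seed)
    positions = rng.choice(params.n_samples, size=n_replace, replace=False)
    x = x.copy()
    x[positions] = rng.uniform(params.noise_low, params.noise_high, size=n_replace)
    return x


def white_gaussian_noise(spec: NoiseSpec) -> np.ndarray:
    """I.i.d. standard normal samples (flat spectrum)."""
    rng = np.random.default_rng(spec.seed)
    return rng.standard_normal(spec.length)


def one_over_f_noise(spec: NoiseSpec) -> np.ndarray:
    """1/f (pink) noise with unit standard deviation.

    White Gaussian noise is shaped in the frequency domain by 1/sqrt(f)
    (power spectral density proportional to 1/f; the DC bin is zeroed),
    inverse-transformed, and standardized to unit SD.
    """
    if spec.length < 4:
        raise ValueError("1/f noise needs length >= 4")
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(spec.length)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(spec.length)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spectrum * shaping, n=spec.length)
    sd = x.std()
    if sd == 0:  # pragma: no cover - requires a zero draw of every bin
        raise ValueError("degenerate 1/f realization with zero variance")
    return x / sd


def add_noise_snr(signal: np.ndarray, snr_db: float, seed: int = 0) -> np.ndarray:
    """Superimpose white Gaussian noise at an exact realized SNR (dB).

    The noise realization is rescaled so that
    ``10 log10(P_signal / P_noise)`` equals ``snr_db`` exactly.
    ``snr_db = inf`` returns the signal unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if np.isinf(snr_db) and snr_db > 0:
        return signal.copy()
    p_signal = float(np.mean(signal**2))
    if p_signal == 0:
        raise ValueError("signal has zero power; SNR undefined")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(signal.size)
    p_noise_target = p_signal / 10.0 ** (snr_db / 10.0)
    noise *= np.sqrt(p_noise_target / np.mean(noise**2))
    return signal + noise
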