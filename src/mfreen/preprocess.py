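"""Band decomposition, per-band standardization, and windowing.

Bridges a single raw signal to the ``N x g`` multiband matrix the entropy
estimators consume. Bandpass filtering uses a windowed-sinc FIR applied
forward and backward (zero phase), the convention of EEG toolboxes; default
bands are the theta (4-8 Hz), alpha (8-13 Hz) and beta (13-30 Hz) EEG rhythms.

Per-band standardization matters: without it a band whose amplitude dwarfs
the others dominates every pairwise distance and biases the rank-pattern
distribution of the multi-frequency entropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .core import MultibandSeries

__all__ = [
    "BandDefinition",
    "SegmentSpec",
    "DEFAULT_BANDS",
    "bandpass_filter",
    "band_decompose",
    "segment",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band: label and [low_hz, high_hz) passband edges."""

    label: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"band {self.label!r}: need 0 < low_hz < high_hz, "
                f"got ({self.low_hz}, {self.high_hz})"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


@dataclass(frozen=True)
class SegmentSpec:
    """Windowing: length 200 / step 200 for non-overlapping resting-state
    intervals, step 1 for sliding task-state analysis."""

    window_len: int = 200
    step: int = 200

    def __post_init__(self):
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not 1 <= self.step <= self.window_len:
            raise ValueError("need 1 <= step <= window_len")


def _fir_order(low_hz: float, sample_rate_hz: float) -> int:
    """Windowed-sinc order: 3 cycles of the low band edge."""
    order = 3 * int(sample_rate_hz / low_hz)
    if order % 2:
        order -= 1  # even order -> odd tap count (type I linear phase)
    if order < 4:
        raise ValueError(
            f"low edge {low_hz} Hz too close to the sampling rate "
            f"{sample_rate_hz} Hz for a usable FIR order"
        )
    return order


def bandpass_filter(
    signal: Sequence[float],
    band: BandDefinition,
    sample_rate_hz: float,
    order: int | None = None,
) -> np.ndarray:
    """Zero-phase FIR bandpass: windowed-sinc design, forward-backward pass.

    Output length equals input length; passband gain is ~1 (the two passes
    square the magnitude response, which is near 1 in the passband). The
    filter order depends only on the band and sampling rate, never on the
    record length, so records of different lengths see the same filter;
    the edge padding of the backward pass is clamped for short records
    (their band estimates carry larger edge transients).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < 16:
        raise ValueError(
            f"signal of length {x.size} too short to bandpass filter"
        )
    nyquist = sample_rate_hz / 2.0
    if band.high_hz >= nyquist:
        raise ValueError(
            f"band {band.label!r} upper edge {band.high_hz} Hz at or above "
            f"Nyquist ({nyquist} Hz)"
        )
    if order is None:
        order = _fir_order(band.low_hz, sample_rate_hz)
    taps = sps.firwin(
        order + 1,
        [band.low_hz, band.high_hz],
        pass_zero=False,
        fs=sample_rate_hz,
    )
    padlen = min(3 * (order + 1), x.size - 1)
    return sps.filtfilt(taps, [1.0], x, padlen=padlen)


def band_decompose(
    signal: Sequence[float],
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    sample_rate_hz: float = 500.0,
    standardize: bool = True,
    order: int | None = None,
    scope: str = "band",
) -> MultibandSeries:
    """Filter a single signal into each band and normalize.

    Column order follows the band list. With ``standardize=True`` and
    ``scope="band"`` (the default) each band column is z-scored to mean 0,
    SD 1 — no band can dominate the others by sheer amplitude. With
    ``scope="channel"`` the whole channel is z-scored before filtering and
    the bands keep that common scale, preserving the relative power of the
    bands; cross-band entropy then also sees which rhythms carry more
    energy, which is what distinguishes, e.g., flat-spectrum from 1/f
    signals.

    One FIR order — set by the lowest band edge in the list — is used for
    every band, so all bands see the same transition sharpness; per-band
    orders would give the wider bands leakier skirts and confound cross-band
    comparisons.
    """
    if len(bands) < 2:
        raise ValueError("band_decompose needs at least 2 bands")
    if scope not in ("band", "channel"):
        raise ValueError("scope must be 'band' or 'channel'")
    x = np.asarray(signal, dtype=float)
    if order is None:
        order = _fir_order(min(b.low_hz for b in bands), sample_rate_hz)
    if standardize and scope == "channel":
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError("channel has zero variance; cannot standardize")
        x = (x - x.mean()) / sd
    columns = []
    for band in bands:
        y = bandpass_filter(x, band, sample_rate_hz, order=order)
        if standardize and scope == "band":
            sd = y.std(ddof=0)
            if sd == 0:
                raise ValueError(
                    f"band {band.label!r} has zero variance; cannot standardize"
                )
            y = (y - y.mean()) / sd
        columns.append(y)
    return MultibandSeries(
        values=np.column_stack(columns),
        band_labels=tuple(b.label for b in bands),
        sample_rate_hz=sample_rate_hz,
    )


def segment(series: MultibandSeries, spec: SegmentSpec) -> list[MultibandSeries]:
    """Cut a multiband series into windows at offsets 0, step, 2*step, ...

    The last partial window is dropped; the count is
    ``floor((N - window_len) / step) + 1``.
    """
    N = series.n_samples
    if spec.window_len > N:
        raise ValueError(
            f"window_len={spec.window_len} exceeds series length {N}"
        )
    count = (N - spec.window_len) // spec.step + 1
    return [
        MultibandSeries(
            values=series.values[off : off + spec.window_len],
            band_labels=series.band_labels,
            sample_rate_hz=series.sample_rate_hz,
        )
        for off in (i * spec.step for i in range(count))
    ]
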