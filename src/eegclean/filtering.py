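"""Zero-phase FIR filtering and linear-trend diagnostics.

The high-pass here is only ever applied to *temporary* copies of the signal:
the pipeline output itself is never committed to a filtering strategy.  The
kernel is a Hamming-windowed sinc applied symmetrically (odd length, linear
phase, delay compensated), with reflect padding of one kernel length so that
edge transients do not leak into windowed statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .model import Recording

__all__ = [
    "FilterSpec",
    "design_kernel",
    "filter_array",
    "fir_filter",
    "TrendFit",
    "fit_linear_trend",
    "remove_linear_trend",
]


@dataclass(frozen=True)
class FilterSpec:
    kind: str                  # 'highpass' or 'lowpass'
    cutoff_hz: float
    transition_hz: float

    def __post_init__(self):
        if self.kind not in ("highpass", "lowpass"):
            raise ValueError(f"kind must be 'highpass' or 'lowpass', got {self.kind!r}")
        if self.cutoff_hz <= 0 or self.transition_hz <= 0:
            raise ValueError("cutoff and transition width must be positive")


def design_kernel(spec: FilterSpec, fs: float) -> np.ndarray:
    """Odd-length, symmetric (linear-phase) Hamming-window FIR kernel.

    Length is at least 3 x fs / transition_hz, the usual windowed-sinc
    heuristic; gain is -6 dB at the cutoff.
    """
    if spec.cutoff_hz >= fs / 2:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    numtaps = int(np.ceil(3.0 * fs / spec.transition_hz))
    if numtaps % 2 == 0:
        numtaps += 1
    lowpass = sps.firwin(numtaps, spec.cutoff_hz, window="hamming", fs=fs)
    lowpass /= lowpass.sum()          # unit DC gain, exactly
    if spec.kind == "lowpass":
        return lowpass
    highpass = -lowpass               # spectral inversion: zero DC gain, exactly
    highpass[numtaps // 2] += 1.0
    return highpass


def filter_array(data: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase filter along the last axis with reflect padding."""
    kernel = design_kernel(spec, fs)
    pad = len(kernel)
    x = np.atleast_2d(np.asarray(data, dtype=np.float64))
    padded = np.concatenate(
        [x[:, pad:0:-1], x, x[:, -2:-pad - 2:-1]], axis=1
    )
    out = sps.fftconvolve(padded, kernel[None, :], mode="same", axes=1)
    out = out[:, pad:pad + x.shape[1]]
    return out[0] if np.ndim(data) == 1 else out


def fir_filter(recording: Recording, spec: FilterSpec) -> Recording:
    return recording.with_data(filter_array(recording.data, recording.fs, spec))


@dataclass(frozen=True)
class TrendFit:
    """Least-squares line fit of a channel against sample index."""

    slope: float          # microvolts per sample
    intercept: float
    correlation: float    # Pearson r between the channel and its fitted line
    degenerate: bool = False


def fit_linear_trend(channel: np.ndarray) -> TrendFit:
    x = np.asarray(channel, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("fit_linear_trend expects a single channel")
    n = len(x)
    t = np.arange(n, dtype=np.float64)
    slope, intercept = np.polyfit(t, x, 1)
    line = slope * t + intercept
    sx = x.std()
    sl = line.std()
    if sx == 0 or sl == 0:
        return TrendFit(float(slope), float(intercept), 0.0, degenerate=True)
    r = float(np.dot(x - x.mean(), line - line.mean()) / (n * sx * sl))
    return TrendFit(float(slope), float(intercept), float(np.clip(r, -1.0, 1.0)))


def remove_linear_trend(recording: Recording) -> Recording:
    t = np.arange(recording.n_samples, dtype=np.float64)
    coeffs = np.polyfit(t, recording.data.T, 1)  # (2, n_channels)
    trend = coeffs[0][:, None] * t[None, :] + coeffs[1][:, None]
    return recording.with_data(recording.data - trend)
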