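"""Parameter dataclasses for every pipeline stage, with the published defaults."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "LineNoiseParams",
    "NoisyChannelParams",
    "ReferenceParams",
    "ReportParams",
    "PipelineConfig",
    "config_to_flat_dict",
    "config_from_flat_dict",
]


@dataclass
class LineNoiseParams:
    """Multitaper harmonic-regression line-noise removal settings."""

    line_frequencies_hz: Optional[tuple[float, ...]] = None  # None -> 60 Hz harmonics
    window_seconds: float = 4.0
    slide_seconds: float = 1.0
    taper_bandwidth_hz: float = 2.0
    p_threshold: float = 0.01
    f_scan_bandwidth_hz: float = 2.0
    tau: float = 100.0            # sigmoid stitching constant, in samples
    max_iterations: int = 10
    detection_highpass_hz: float = 1.0
    # a frequency is retired once insignificant in at least this fraction of
    # windows; 0.95 keeps chance-level F-test hits (p_threshold per window)
    # from holding a frequency active through every iteration
    insignificant_window_fraction: float = 0.95

    def candidate_frequencies(self, fs: float) -> tuple[float, ...]:
        if self.line_frequencies_hz is not None:
            return tuple(f for f in self.line_frequencies_hz if f < fs / 2)
        base = 60.0
        freqs = []
        f = base
        while f < fs / 2:
            freqs.append(f)
            f += base
        return tuple(freqs)


@dataclass
class NoisyChannelParams:
    """Thresholds for the noisy-channel criterion battery."""

    robust_deviation_threshold: float = 5.0
    correlation_window_seconds: float = 1.0
    correlation_threshold: float = 0.4
    bad_time_fraction: float = 0.01
    correlation_percentile: float = 98.0
    hf_noise_threshold: float = 5.0
    hf_split_hz: float = 50.0
    ransac_subset_fraction: float = 0.25
    ransac_correlation_threshold: float = 0.75
    ransac_bad_fraction: float = 0.4
    ransac_window_seconds: float = 5.0
    ransac_sample_count: int = 50
    dropout_fraction: float = 0.01
    detection_highpass_hz: float = 1.0
    run_ransac: bool = True


@dataclass
class ReferenceParams:
    """Two-phase robust average referencing settings."""

    initial_estimate: str = "median"    # 'median' or 'mean'
    max_iterations: int = 4
    # fraction of evaluation channels that may accumulate as bad before abort
    max_bad_fraction: float = 0.75


@dataclass
class ReportParams:
    window_seconds: float = 1.0


@dataclass
class PipelineConfig:
    line_noise: LineNoiseParams = field(default_factory=LineNoiseParams)
    noisy: NoisyChannelParams = field(default_factory=NoisyChannelParams)
    reference: ReferenceParams = field(default_factory=ReferenceParams)
    report: ReportParams = field(default_factory=ReportParams)
    seed: int = 0


_SECTIONS = ("line_noise", "noisy", "reference", "report")


def config_to_flat_dict(config: PipelineConfig) -> dict:
    """Flatten a config into dotted ``section.key`` scalars (for files/attrs)."""
    out: dict = {"seed": config.seed}
    for section in _SECTIONS:
        params = getattr(config, section)
        for f in dataclasses.fields(params):
            value = getattr(params, f.name)
            if isinstance(value, tuple):
                value = list(value)
            out[f"{section}.{f.name}"] = value
    return out


def config_from_flat_dict(flat: dict) -> PipelineConfig:
    """Inverse of :func:`config_to_flat_dict`; unknown keys are rejected."""
    config = PipelineConfig()
    for key, value in flat.items():
        if key == "seed":
            config.seed = int(value)
            continue
        try:
            section, name = key.split(".", 1)
        except ValueError:
            raise KeyError(f"unrecognized config key {key!r}") from None
        if section not in _SECTIONS:
            raise KeyError(f"unrecognized config section {section!r}")
        params = getattr(config, section)
        if not hasattr(params, name):
            raise KeyError(f"unrecognized config key {key!r}")
        current = getattr(params, name)
        if isinstance(value, str):
            value = _coerce(value, current)
        elif isinstance(value, (list, tuple)):
            value = tuple(float(v) for v in value)
        setattr(params, name, value)
    return config


def _coerce(text: str, current):
    text = text.strip()
    if isinstance(current, bool):
        return text.lower() in ("1", "true", "yes", "on")
    if isinstance(current, int):
        return int(text)
    if isinstance(current, float):
        return float(text)
    if current is None or isinstance(current, tuple):
        if text.lower() in ("", "none"):
            return None
        return tuple(float(v) for v in text.split(","))
    return text
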