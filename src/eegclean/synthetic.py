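"""Synthetic EEG generation, ground-truth bad-channel injection, and scoring.

The generator produces spatially correlated multichannel EEG from 1/f sources
mixed through a smooth distance-decay gain model, plus per-channel drift,
non-stationary 60 Hz line noise, and a sensor noise floor.  The benchmark
builder reproduces the five-session injection design (Gaussian noise at 8x
channel SD, one-tenth amplitude, temporal shuffling, and fully correlated
channel pairs) and the scorer computes sensitivity/specificity over all
channel decisions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .filtering import FilterSpec, filter_array
from .linenoise import remove_line_noise_filtered
from .model import Montage, Recording
from .montages import standard_cap_32
from .noisy import NoisyChannelResult, find_noisy_channels, robust_sd
from .params import LineNoiseParams, NoisyChannelParams

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "DetectionScore",
    "generate_clean",
    "inject",
    "build_benchmark",
    "score_detection",
    "run_benchmark",
    "BENCHMARK_SESSIONS",
]

# session id -> channel counts (gaussian, low_amplitude, shuffled, correlated)
# the last column counts channels, two per fully correlated pair
BENCHMARK_SESSIONS = (
    ("5", 3, 1, 1, 2),
    ("14", 3, 1, 1, 2),
    ("30", 4, 1, 1, 2),
    ("31", 5, 1, 2, 2),
    ("68", 5, 1, 2, 2),
)

NOISE_TYPES = ("gaussian", "low_amplitude", "shuffled", "correlated_pair")


@dataclass
class SyntheticSpec:
    n_channels: int = 32
    duration_seconds: float = 300.0
    fs: float = 200.0
    montage: Montage | None = None
    source_count: int = 40
    # gain = exp(-d^2 / (2 sigma^2)), d = chord distance; 0.5 keeps neighbors
    # correlated without letting one global common mode dominate every channel
    mixing_sigma: float = 0.5
    source_depth: float = 0.8
    signal_sd: float = 20.0          # microvolts, per channel
    signal_sd_jitter: float = 0.05
    noise_floor_sd: float = 1.0
    noise_floor_jitter: float = 0.02
    line_frequency_hz: float = 60.0
    line_amplitude: float = 4.0
    drift_slope_range: tuple[float, float] = (-1.0, 8.0)   # microvolts / second
    drift_wander_sd: float = 100.0
    seed: int = 0

    def resolve_montage(self) -> Montage:
        if self.montage is not None:
            if len(self.montage) != self.n_channels:
                raise ValueError("montage size does not match n_channels")
            return self.montage
        if self.n_channels != 32:
            raise ValueError("only the bundled 32-channel layout is built in; pass a montage")
        return standard_cap_32()


@dataclass(frozen=True)
class GroundTruth:
    session_id: str
    injected: dict  # channel label -> noise type

    @property
    def bad_channels(self) -> frozenset:
        return frozenset(self.injected)


def _shaped_noise(rng, shape, fs, amplitude_of_f) -> np.ndarray:
    """Gaussian noise with the given one-sided spectral amplitude profile."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = amplitude_of_f(f)
    x = np.fft.irfft(spec * amp, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _pink(rng, shape, fs):
    return _shaped_noise(rng, shape, fs, lambda f: np.where(f > 0, 1.0 / np.sqrt(np.maximum(f, 0.5)), 0.0))


def _slow(rng, shape, fs, f_c):
    return _shaped_noise(rng, shape, fs, lambda f: np.where(f > 0, np.exp(-((f / f_c) ** 2)), 0.0))


def generate_clean(spec: SyntheticSpec | None = None, seed: int | None = None) -> Recording:
    """Deterministic clean recording: correlated 1/f EEG + drift + line noise."""
    spec = spec or SyntheticSpec()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    montage = spec.resolve_montage().normalized()
    fs = spec.fs
    n = int(round(spec.duration_seconds * fs))
    c = spec.n_channels
    t = np.arange(n) / fs

    # smooth source field: gains decay with chord distance electrode<->source
    dirs = rng.standard_normal((spec.source_count, 3))
    dirs[:, 2] = np.abs(dirs[:, 2]) * 0.8 + 0.2      # bias sources upward
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    src_pos = spec.source_depth * dirs
    d2 = ((montage.positions[:, None, :] - src_pos[None, :, :]) ** 2).sum(axis=2)
    gains = np.exp(-d2 / (2.0 * spec.mixing_sigma**2))

    sources = _pink(rng, (spec.source_count, n), fs)
    brain = gains @ sources
    brain /= brain.std(axis=1, keepdims=True)
    sd = spec.signal_sd * (1.0 + spec.signal_sd_jitter * rng.standard_normal(c))
    brain *= sd[:, None]

    noise_sd = spec.noise_floor_sd * (
        1.0 + spec.noise_floor_jitter * rng.standard_normal(c)
    )
    sensor = rng.standard_normal((c, n)) * noise_sd[:, None]

    env = 1.0 + 0.3 * _slow(rng, (n,), fs, 0.05)
    env = np.clip(env, 0.1, None)
    phase_wander = 0.6 * _slow(rng, (n,), fs, 0.05)
    amp = spec.line_amplitude * (0.8 + 0.4 * rng.random(c))
    psi = 0.1 * rng.standard_normal(c)
    line = amp[:, None] * env[None, :] * np.cos(
        2 * np.pi * spec.line_frequency_hz * t[None, :]
        + phase_wander[None, :]
        + psi[:, None]
    )

    lo, hi = spec.drift_slope_range
    slopes = rng.uniform(lo, hi, size=c)
    drift = slopes[:, None] * t[None, :]
    drift += spec.drift_wander_sd * _slow(rng, (c, n), fs, 0.02)

    data = brain + sensor + line + drift
    return Recording(data, fs, montage)


def inject(
    recording: Recording,
    truth: GroundTruth,
    rng: np.random.Generator | int | None = None,
    donor_signal: np.ndarray | None = None,
) -> Recording:
    """Apply the ground-truth noise plan to a copy of the recording.

    ``donor_signal`` supplies the external channel used for the fully
    correlated pair; it is repeated or trimmed to the session length and
    amplitude-normalized to each replaced channel's robust SD.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    unknown = set(truth.injected) - set(recording.montage.labels)
    if unknown:
        raise KeyError(f"injection plan references unknown channels: {sorted(unknown)}")
    bad_types = set(truth.injected.values()) - set(NOISE_TYPES)
    if bad_types:
        raise ValueError(f"unknown noise types: {sorted(bad_types)}")
    data = recording.data.copy()
    n = data.shape[1]
    pair = [l for l, k in truth.injected.items() if k == "correlated_pair"]
    if pair and donor_signal is None:
        raise ValueError("correlated_pair injection requires a donor signal")
    for label, kind in truth.injected.items():
        i = recording.montage.index(label)
        if kind == "gaussian":
            data[i] = data[i] + 8.0 * data[i].std() * rng.standard_normal(n)
        elif kind == "low_amplitude":
            data[i] = 0.1 * data[i]
        elif kind == "shuffled":
            data[i] = rng.permutation(data[i])
        elif kind == "correlated_pair":
            donor = np.asarray(donor_signal, dtype=np.float64)
            reps = math.ceil(n / len(donor))
            donor = np.tile(donor, reps)[:n]
            scale = robust_sd(data[i]) / robust_sd(donor)
            data[i] = donor * scale
    return recording.with_data(data)


def _preprocess_base(raw: Recording, line_params: LineNoiseParams) -> Recording:
    """1 Hz high-pass followed by line-noise removal (the benchmark base data)."""
    hp = FilterSpec("highpass", line_params.detection_highpass_hz,
                    line_params.detection_highpass_hz)
    filtered = raw.with_data(filter_array(raw.data, raw.fs, hp))
    clean, _ = remove_line_noise_filtered(filtered, line_params)
    return clean


def build_benchmark(
    seed: int,
    spec: SyntheticSpec | None = None,
    line_params: LineNoiseParams | None = None,
) -> list[tuple[Recording, GroundTruth]]:
    """Five preprocessed sessions with fixed per-type injection counts.

    Each session is generated clean, high-passed at 1 Hz, line-noise removed,
    and then injected.  The correlated-pair donor is the highest-robust-SD
    channel of a different session in the same benchmark.
    """
    spec = spec or SyntheticSpec()
    line_params = line_params or LineNoiseParams()
    seeds = np.random.SeedSequence(seed).spawn(len(BENCHMARK_SESSIONS) + 1)
    pick_rng = np.random.default_rng(seeds[-1])
    bases = []
    for i, _session in enumerate(BENCHMARK_SESSIONS):
        raw = generate_clean(spec, seed=seeds[i])
        bases.append(_preprocess_base(raw, line_params))

    out = []
    for i, (session_id, n_gauss, n_low, n_shuf, n_pair) in enumerate(BENCHMARK_SESSIONS):
        if n_pair % 2:
            raise ValueError("correlated channels come in pairs")
        base = bases[i]
        labels = list(base.montage.labels)
        total = n_gauss + n_low + n_shuf + n_pair
        chosen = list(pick_rng.choice(labels, size=total, replace=False))
        plan: dict = {}
        for _ in range(n_gauss):
            plan[chosen.pop()] = "gaussian"
        for _ in range(n_low):
            plan[chosen.pop()] = "low_amplitude"
        for _ in range(n_shuf):
            plan[chosen.pop()] = "shuffled"
        for _ in range(n_pair):
            plan[chosen.pop()] = "correlated_pair"
        truth = GroundTruth(session_id, plan)

        donor_base = bases[(i + 1) % len(bases)]
        donor_idx = int(np.argmax(robust_sd(donor_base.data, axis=1)))
        donor = donor_base.data[donor_idx]
        out.append((inject(base, truth, pick_rng, donor_signal=donor), truth))
    return out


@dataclass(frozen=True)
class DetectionScore:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_decisions(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def score_detection(results, truths) -> DetectionScore:
    """Confusion counts over every channel decision across sessions."""
    results = list(results)
    truths = list(truths)
    if len(results) != len(truths):
        raise ValueError(
            f"{len(results)} detection results but {len(truths)} ground truths"
        )
    tp = fp = tn = fn = 0
    for result, truth in zip(results, truths):
        if isinstance(result, NoisyChannelResult):
            predicted = set(result.all_bad)
            channels = result.channels
        else:  # plain iterable of predicted-bad labels + channel list required
            predicted, channels = result
            predicted = set(predicted)
        actual = truth.bad_channels
        for ch in channels:
            if ch in actual:
                if ch in predicted:
                    tp += 1
                else:
                    fn += 1
            else:
                if ch in predicted:
                    fp += 1
                else:
                    tn += 1
    return DetectionScore(tp, fp, tn, fn)


def run_benchmark(
    seed: int,
    spec: SyntheticSpec | None = None,
    noisy_params: NoisyChannelParams | None = None,
    line_params: LineNoiseParams | None = None,
):
    """Build, detect, and score one benchmark replicate.

    Returns ``(score, sessions, results)``.
    """
    noisy_params = noisy_params or NoisyChannelParams()
    sessions = build_benchmark(seed, spec, line_params)
    results = [
        find_noisy_channels(rec, noisy_params, np.random.default_rng(seed + 17 * i))
        for i, (rec, _t) in enumerate(sessions)
    ]
    score = score_detection(results, [t for _r, t in sessions])
    return score, sessions, results
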