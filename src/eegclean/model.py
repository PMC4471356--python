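"""Core data model: montages, recordings, and window partitioning.

All signal data is held as channels x samples float64 arrays in microvolts.
Single-precision input is up-cast (with a warning) on construction because the
downstream referencing arithmetic is not reliable in float32.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Montage",
    "Recording",
    "WindowGrid",
    "partition_windows",
    "PrecisionWarning",
]


class PrecisionWarning(UserWarning):
    """Raised when single-precision data is up-cast to double."""


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels with 3-D Cartesian electrode positions.

    Position units are arbitrary; :meth:`normalized` projects radially onto
    the unit sphere, which is the geometry the spline interpolation assumes.
    """

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "labels", labels)
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError(f"positions must be (n, 3), got {pos.shape}")
        if len(labels) != pos.shape[0]:
            raise ValueError(
                f"{len(labels)} labels but {pos.shape[0]} positions"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        if any(not l for l in labels):
            raise ValueError("channel labels must be non-empty")
        if not np.all(np.isfinite(pos)):
            raise ValueError("electrode positions must be finite")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise ValueError("electrode positions must have nonzero norm")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.index(l) for l in labels], dtype=np.intp)

    def normalized(self) -> "Montage":
        """Radial projection of all positions onto the unit sphere."""
        norms = np.linalg.norm(self.positions, axis=1, keepdims=True)
        return Montage(self.labels, self.positions / norms)

    def subset(self, labels: Sequence[str]) -> "Montage":
        idx = self.indices(labels)
        return Montage(tuple(labels), self.positions[idx])


@dataclass
class Recording:
    """A continuous multichannel EEG segment.

    ``data`` is channels x samples in microvolts, row order matching
    ``montage.labels``.  ``evaluation_channels`` names the subset treated as
    EEG proper (everything by default); mastoids/EOG are excluded by listing
    only the scalp channels here.
    """

    data: np.ndarray
    fs: float
    montage: Montage
    evaluation_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.dtype != np.float64:
            if data.dtype in (np.float32, np.float16):
                warnings.warn(
                    "up-casting signal data to float64; double precision is "
                    "required for reference arithmetic",
                    PrecisionWarning,
                    stacklevel=3,
                )
            data = np.ascontiguousarray(data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got {data.ndim}-D")
        if data.shape[0] != len(self.montage):
            raise ValueError(
                f"data has {data.shape[0]} rows but montage has "
                f"{len(self.montage)} channels"
            )
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"sampling rate must be positive and finite, got {self.fs}")
        if data.shape[0] < 2:
            raise ValueError("a recording needs at least 2 channels")
        if data.shape[1] < self.fs:
            raise ValueError("a recording needs at least one second of data")
        self.data = data
        self.fs = float(self.fs)
        if not self.evaluation_channels:
            self.evaluation_channels = tuple(self.montage.labels)
        else:
            self.evaluation_channels = tuple(self.evaluation_channels)
            missing = set(self.evaluation_channels) - set(self.montage.labels)
            if missing:
                raise ValueError(f"evaluation channels not in montage: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def eval_indices(self) -> np.ndarray:
        return self.montage.indices(self.evaluation_channels)

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class WindowGrid:
    """Non-overlapping, contiguous windows of equal length.

    The trailing partial window, if any, is discarded.
    """

    window_seconds: float
    size: int                 # samples per window
    starts: np.ndarray        # start sample of each window

    @property
    def count(self) -> int:
        return len(self.starts)

    def slices(self):
        for s in self.starts:
            yield slice(int(s), int(s) + self.size)

    def split(self, data: np.ndarray) -> np.ndarray:
        """View (..., n_samples) data as (..., count, size) windows."""
        used = self.count * self.size
        return data[..., :used].reshape(*data.shape[:-1], self.count, self.size)


def partition_windows(n_samples: int, fs: float, window_seconds: float = 1.0) -> WindowGrid:
    size = int(round(window_seconds * fs))
    if size <= 0:
        raise ValueError("window_seconds x fs must be at least one sample")
    if n_samples < size:
        raise ValueError(
            f"recording of {n_samples} samples is shorter than one "
            f"{window_seconds} s window ({size} samples)"
        )
    count = n_samples // size
    starts = np.arange(count, dtype=np.intp) * size
    return WindowGrid(float(window_seconds), size, starts)
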