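"""Noisy-channel detection: robust statistics and the criterion battery.

Channels are classified as bad by NaN, NoData, dropout, deviation,
correlation, RANSAC (predictability), HF noise, or lowSNR.  Detection always
runs on a temporary 1 Hz high-passed copy; the correlation, RANSAC and
noisiness criteria additionally use a 50 Hz low-passed copy.  Channels that
are unusable (NaN, NoData, lowSNR) are removed from consideration once
detected and never re-tested.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .filtering import FilterSpec, filter_array
from .interpolation import SplineModel, build_interpolation_matrix
from .model import Recording, WindowGrid, partition_windows
from .params import NoisyChannelParams

__all__ = [
    "robust_sd",
    "robust_z",
    "mad",
    "WindowStats",
    "NoisyChannelResult",
    "detect_nan_nodata",
    "detect_deviation",
    "detect_correlation_dropout",
    "detect_hf_noise",
    "detect_ransac",
    "find_noisy_channels",
]

IQR_TO_SD = 0.7413  # normal-consistency factor for the interquartile range
CATEGORIES = (
    "nan", "nodata", "dropout", "deviation", "correlation", "ransac",
    "hf_noise", "low_snr",
)
_TINY_WINDOW_SD = 1e-4  # microvolts; below this a window counts as a dropout


def robust_sd(x, axis=None):
    """0.7413 x interquartile range (linear-interpolation quantiles)."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size if axis is None else x.shape[axis]
    if n < 2:
        raise ValueError("robust_sd needs at least 2 values")
    q75, q25 = np.percentile(x, [75, 25], axis=axis)
    return IQR_TO_SD * (q75 - q25)


def robust_z(values):
    """Robust z-scores (median / robust SD); returns ``(z, degenerate)``.

    If the robust SD is zero the spread is degenerate and all z-scores are
    reported as zero with the flag raised.
    """
    v = np.asarray(values, dtype=np.float64)
    med = np.median(v)
    sd = robust_sd(v)
    if sd == 0:
        return np.zeros_like(v), True
    return (v - med) / sd, False


def mad(x, axis=None):
    """Median absolute deviation (no consistency scaling)."""
    x = np.asarray(x, dtype=np.float64)
    med = np.median(x, axis=axis, keepdims=True)
    return np.median(np.abs(x - med), axis=axis)


@dataclass
class WindowStats:
    """Windowed diagnostic arrays retained for reporting.

    All 1 s arrays are (channels x windows) in evaluation-channel order;
    rows of channels excluded as unusable are NaN.
    """

    deviation_z: np.ndarray
    max_correlation: np.ndarray
    noise_z: np.ndarray
    dropout_flags: np.ndarray
    ransac_correlation: np.ndarray | None
    window_deviation: np.ndarray          # D: 0.7413 x IQR per channel-window
    window_seconds: float = 1.0
    ransac_window_seconds: float = 5.0


@dataclass
class NoisyChannelResult:
    channels: tuple[str, ...]             # evaluation channels, in order
    bad_by: dict[str, frozenset]
    stats: WindowStats
    params: NoisyChannelParams
    notes: dict = field(default_factory=dict)

    @property
    def unusable(self) -> frozenset:
        return self.bad_by["nan"] | self.bad_by["nodata"] | self.bad_by["low_snr"]

    @property
    def all_bad(self) -> frozenset:
        out = frozenset()
        for cat in CATEGORIES:
            out |= self.bad_by[cat]
        return out


# ---------------------------------------------------------------------------
# individual criteria (array-level helpers + Recording-level wrappers)
# ---------------------------------------------------------------------------

def _nan_nodata(x: np.ndarray, fs: float, dropout_fraction: float):
    bad_nan, bad_nodata = [], []
    grid = partition_windows(x.shape[1], fs, 1.0)
    win = grid.split(x)
    const_frac = np.mean(np.ptp(win, axis=2) == 0, axis=1)
    for i in range(x.shape[0]):
        if not np.all(np.isfinite(x[i])):
            bad_nan.append(i)
        elif robust_sd(x[i]) == 0 or const_frac[i] > dropout_fraction:
            bad_nodata.append(i)
    return bad_nan, bad_nodata


def detect_nan_nodata(recording: Recording, params: NoisyChannelParams | None = None):
    """Channels with non-finite samples or significant constant stretches."""
    params = params or NoisyChannelParams()
    idx = recording.eval_indices
    labels = recording.evaluation_channels
    bad_nan, bad_nodata = _nan_nodata(
        recording.data[idx], recording.fs, params.dropout_fraction
    )
    return {
        "nan": frozenset(labels[i] for i in bad_nan),
        "nodata": frozenset(labels[i] for i in bad_nodata),
    }


def _deviation(x: np.ndarray, grid: WindowGrid, threshold: float):
    """Robust amplitude z-scores; returns (bad_rows, z, windowed_z, D, flag)."""
    channel_dev = robust_sd(x, axis=1)
    z, degenerate = robust_z(channel_dev)
    bad = [] if degenerate else list(np.nonzero(np.abs(z) > threshold)[0])
    d = IQR_TO_SD * np.diff(
        np.percentile(grid.split(x), [25, 75], axis=2), axis=0
    )[0]
    med = np.median(channel_dev)
    sd = robust_sd(channel_dev)
    windowed_z = (d - med) / sd if sd > 0 else np.zeros_like(d)
    return bad, z, windowed_z, d, degenerate


def detect_deviation(recording: Recording, params: NoisyChannelParams | None = None):
    params = params or NoisyChannelParams()
    idx = recording.eval_indices
    labels = recording.evaluation_channels
    grid = partition_windows(recording.n_samples, recording.fs, 1.0)
    bad, z, wz, d, degenerate = _deviation(
        recording.data[idx], grid, params.robust_deviation_threshold
    )
    return frozenset(labels[i] for i in bad), wz, {"degenerate": degenerate, "z": z}


def _window_correlations(x_lp: np.ndarray, grid: WindowGrid, percentile: float):
    """98th-percentile absolute window correlations, (channels x windows).

    Pearson correlation with a constant window is defined as 0.
    """
    c = x_lp.shape[0]
    win = grid.split(x_lp)                            # (c, w, s)
    centered = win - win.mean(axis=2, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=2))
    safe = np.where(norm > 0, norm, 1.0)
    unit = centered / safe[:, :, None]
    corr = np.einsum("iws,jws->wij", unit, unit, optimize=True)
    corr = np.abs(corr)
    mask = ~np.eye(c, dtype=bool)
    offdiag = corr[:, mask].reshape(grid.count, c, c - 1)
    maxcorr = np.percentile(offdiag, percentile, axis=2).T   # (c, w)
    window_sd = IQR_TO_SD * np.diff(
        np.percentile(win, [25, 75], axis=2), axis=0
    )[0]
    dropout = window_sd < _TINY_WINDOW_SD
    return maxcorr, dropout


def detect_correlation_dropout(
    recording: Recording, params: NoisyChannelParams | None = None, *,
    lowpassed: bool = False,
):
    """bad-by-correlation / bad-by-dropout on the 50 Hz low-passed copy."""
    params = params or NoisyChannelParams()
    idx = recording.eval_indices
    labels = recording.evaluation_channels
    if len(idx) < 2:
        raise ValueError("correlation criterion needs at least 2 channels")
    x = recording.data[idx]
    if not lowpassed:
        x = filter_array(x, recording.fs, FilterSpec("lowpass", params.hf_split_hz, 5.0))
    grid = partition_windows(
        recording.n_samples, recording.fs, params.correlation_window_seconds
    )
    maxcorr, dropout = _window_correlations(x, grid, params.correlation_percentile)
    bad_frac = np.mean(maxcorr < params.correlation_threshold, axis=1)
    bad_corr = frozenset(
        labels[i] for i in np.nonzero(bad_frac > params.bad_time_fraction)[0]
    )
    drop_frac = np.mean(dropout, axis=1)
    bad_drop = frozenset(
        labels[i] for i in np.nonzero(drop_frac > params.dropout_fraction)[0]
    )
    return bad_corr, bad_drop, maxcorr, dropout


def _hf_noise(x: np.ndarray, x_lp: np.ndarray, grid: WindowGrid, threshold: float):
    hf = x - x_lp
    with np.errstate(divide="ignore", invalid="ignore"):
        noisiness = mad(hf, axis=1) / mad(x_lp, axis=1)
    noisiness = np.nan_to_num(noisiness, nan=np.inf)
    finite = noisiness[np.isfinite(noisiness)]
    z, degenerate = robust_z(np.where(np.isfinite(noisiness), noisiness, np.max(finite, initial=0.0) * 10))
    bad = [] if degenerate else list(np.nonzero(z > threshold)[0])
    # windowed noisiness z, scored against the whole-record channel statistics
    w_hf = mad(grid.split(hf), axis=2)
    w_lf = mad(grid.split(x_lp), axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ratio = np.nan_to_num(w_hf / w_lf, nan=0.0, posinf=0.0)
    med = np.median(noisiness[np.isfinite(noisiness)])
    sd = robust_sd(noisiness[np.isfinite(noisiness)])
    windowed_z = (w_ratio - med) / sd if sd > 0 else np.zeros_like(w_ratio)
    return bad, z, windowed_z, degenerate


def detect_hf_noise(recording: Recording, params: NoisyChannelParams | None = None):
    params = params or NoisyChannelParams()
    if recording.fs <= 2 * params.hf_split_hz:
        raise ValueError(
            f"sampling rate {recording.fs} Hz cannot resolve a "
            f"{params.hf_split_hz} Hz high/low split"
        )
    idx = recording.eval_indices
    labels = recording.evaluation_channels
    x = recording.data[idx]
    x_lp = filter_array(x, recording.fs, FilterSpec("lowpass", params.hf_split_hz, 5.0))
    grid = partition_windows(recording.n_samples, recording.fs, 1.0)
    bad, z, wz, degenerate = _hf_noise(x, x_lp, grid, params.hf_noise_threshold)
    return frozenset(labels[i] for i in bad), wz, {"degenerate": degenerate, "z": z}


def _ransac(
    x_lp: np.ndarray,
    fs: float,
    positions: np.ndarray,
    targets: np.ndarray,
    pool: np.ndarray,
    params: NoisyChannelParams,
    rng: np.random.Generator,
):
    """Predict each target channel from random predictor subsets.

    Returns (bad_rows, correlations (c x w) with NaN off-target, terminated).
    """
    n = x_lp.shape[1]
    grid = partition_windows(n, fs, params.ransac_window_seconds)
    corr = np.full((x_lp.shape[0], grid.count), np.nan)
    n_pred = math.ceil(params.ransac_subset_fraction * len(pool))
    bad = []
    for ti in targets:
        pool_t = np.array([p for p in pool if p != ti])
        if len(pool_t) < n_pred or n_pred < 3:
            return [], corr, True      # cannot form subsets: terminate
        preds = np.empty((params.ransac_sample_count, n))
        for s in range(params.ransac_sample_count):
            subset = rng.choice(pool_t, size=n_pred, replace=False)
            weights = build_interpolation_matrix(
                SplineModel(positions[subset], positions[[ti]])
            )
            preds[s] = weights @ x_lp[subset]
        pred = np.median(preds, axis=0)
        pw = grid.split(pred)
        aw = grid.split(x_lp[ti])
        pc = pw - pw.mean(axis=1, keepdims=True)
        ac = aw - aw.mean(axis=1, keepdims=True)
        denom = np.sqrt((pc**2).sum(axis=1) * (ac**2).sum(axis=1))
        r = np.where(denom > 0, (pc * ac).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
        corr[ti] = r
        frac_bad = np.mean(r < params.ransac_correlation_threshold)
        if frac_bad > params.ransac_bad_fraction:
            bad.append(ti)
    return bad, corr, False


def detect_ransac(
    recording: Recording,
    exclude=(),
    params: NoisyChannelParams | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    lowpassed: bool = False,
):
    """bad-by-RANSAC via spherical-spline prediction from random subsets."""
    params = params or NoisyChannelParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = recording.evaluation_channels
    idx = recording.eval_indices
    montage = recording.montage.normalized()
    positions = montage.positions[idx]
    x = recording.data[idx]
    if not lowpassed:
        x = filter_array(x, recording.fs, FilterSpec("lowpass", params.hf_split_hz, 5.0))
    exclude = set(exclude)
    pool = np.array([i for i, l in enumerate(labels) if l not in exclude])
    targets = pool
    bad, corr, terminated = _ransac(x, recording.fs, positions, targets, pool, params, rng)
    return frozenset(labels[i] for i in bad), corr, {"terminated": terminated}


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def find_noisy_channels(
    recording: Recording,
    params: NoisyChannelParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> NoisyChannelResult:
    """Run the full criterion battery on a temporary 1 Hz high-passed copy.

    Order: NaN/NoData -> deviation -> correlation/dropout -> HF noise ->
    lowSNR promotion -> RANSAC.  Unusable channels (NaN, NoData, lowSNR) are
    excluded from every later criterion and from the RANSAC predictor pool.
    """
    params = params or NoisyChannelParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = recording.evaluation_channels
    idx = recording.eval_indices
    c = len(labels)
    fs = recording.fs
    raw = recording.data[idx]
    notes: dict = {}

    bad_nan, bad_nodata = _nan_nodata(raw, fs, params.dropout_fraction)
    usable = np.array(
        [i for i in range(c) if i not in set(bad_nan) | set(bad_nodata)],
        dtype=np.intp,
    )
    if len(usable) < 2:
        raise ValueError("fewer than 2 usable channels")

    work = raw[usable]
    work = filter_array(
        work, fs, FilterSpec("highpass", params.detection_highpass_hz,
                             params.detection_highpass_hz)
    )
    x_lp = filter_array(work, fs, FilterSpec("lowpass", params.hf_split_hz, 5.0))
    grid1 = partition_windows(recording.n_samples, fs, params.correlation_window_seconds)

    def expand(arr, fill=np.nan):
        out = np.full((c,) + arr.shape[1:], fill, dtype=arr.dtype if arr.dtype != bool else bool)
        out[usable] = arr
        return out

    # deviation
    dev_rows, dev_z, dev_wz, window_dev, dev_degenerate = _deviation(
        work, grid1, params.robust_deviation_threshold
    )
    notes["deviation_degenerate"] = dev_degenerate

    # correlation + dropout
    maxcorr, dropout = _window_correlations(x_lp, grid1, params.correlation_percentile)
    corr_frac = np.mean(maxcorr < params.correlation_threshold, axis=1)
    corr_rows = list(np.nonzero(corr_frac > params.bad_time_fraction)[0])
    drop_rows = list(np.nonzero(np.mean(dropout, axis=1) > params.dropout_fraction)[0])

    # HF noise
    if fs <= 2 * params.hf_split_hz:
        raise ValueError(
            f"sampling rate {fs} Hz cannot resolve a {params.hf_split_hz} Hz split"
        )
    hf_rows, hf_z, hf_wz, hf_degenerate = _hf_noise(
        work, x_lp, grid1, params.hf_noise_threshold
    )
    notes["hf_degenerate"] = hf_degenerate

    # lowSNR: fails both correlation and HF noise -> unusable
    low_snr_rows = sorted(set(corr_rows) & set(hf_rows))

    # RANSAC on channels still in play, predictors = channels clean so far
    ransac_rows: list = []
    ransac_corr_usable = None
    if params.run_ransac:
        flagged = set(dev_rows) | set(corr_rows) | set(hf_rows) | set(drop_rows)
        still_usable = np.array(
            [i for i in range(len(usable)) if i not in set(low_snr_rows)], dtype=np.intp
        )
        pool = np.array([i for i in still_usable if i not in flagged], dtype=np.intp)
        montage = recording.montage.normalized()
        positions = montage.positions[idx][usable]
        ransac_rows, ransac_corr_usable, terminated = _ransac(
            x_lp, fs, positions, still_usable, pool, params, rng
        )
        notes["ransac_terminated"] = terminated

    def to_labels(rows):
        return frozenset(labels[usable[i]] for i in rows)

    bad_by = {
        "nan": frozenset(labels[i] for i in bad_nan),
        "nodata": frozenset(labels[i] for i in bad_nodata),
        "dropout": to_labels(drop_rows),
        "deviation": to_labels(dev_rows),
        "correlation": to_labels(corr_rows),
        "ransac": to_labels(ransac_rows),
        "hf_noise": to_labels(hf_rows),
        "low_snr": to_labels(low_snr_rows),
    }
    stats = WindowStats(
        deviation_z=expand(dev_wz),
        max_correlation=expand(maxcorr),
        noise_z=expand(hf_wz),
        dropout_flags=expand(dropout, fill=False),
        ransac_correlation=(
            expand(ransac_corr_usable) if ransac_corr_usable is not None else None
        ),
        window_deviation=expand(window_dev),
        window_seconds=params.correlation_window_seconds,
        ransac_window_seconds=params.ransac_window_seconds,
    )
    return NoisyChannelResult(tuple(labels), bad_by, stats, params, notes)
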