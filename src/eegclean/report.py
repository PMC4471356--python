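"""Windowed diagnostics, dataset summary measures, and issue flags.

Every summary statistic is a pure function of the windowed arrays retained by
the detection stage, so a report recomputed from a serialized container is
identical to one computed during the live run.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .model import Recording, WindowGrid, partition_windows
from .noisy import IQR_TO_SD, NoisyChannelResult, robust_sd
from .reference import ReferenceResult

__all__ = [
    "DatasetSummary",
    "IssueFlags",
    "compute_window_deviations",
    "stage_summary",
    "summarize",
    "flag_issues",
    "collection_summary",
    "build_report",
]

GOOD_CORRELATION_INTERVAL = (0.80, 0.91)
MEAN_CORRELATION_CEILING = 0.91
MEDIAN_CORRELATION_CEILING = 0.95
MAX_INTERPOLATED_FRACTION = 0.25


@dataclass(frozen=True)
class DatasetSummary:
    mean_max_correlation: float          # grand mean of the c x w array
    median_max_correlation: float        # median of per-channel medians
    mean_median_max_correlation: float   # mean over channels of per-channel medians
    median_window_deviation: float       # overall median of D
    deviation_ratio: float               # robust_sd(D) / median(D)
    interpolated_fraction: float
    reference_correlation: float


@dataclass(frozen=True)
class IssueFlags:
    corr_not_improved: bool
    corr_too_high: bool
    too_many_interpolated: bool

    @property
    def any(self) -> bool:
        return self.corr_not_improved or self.corr_too_high or self.too_many_interpolated


def compute_window_deviations(recording: Recording, grid: WindowGrid | None = None) -> np.ndarray:
    """D[c, w] = 0.7413 x IQR of channel c in window w."""
    if grid is None:
        grid = partition_windows(recording.n_samples, recording.fs, 1.0)
    win = grid.split(recording.data)
    q25, q75 = np.percentile(win, [25, 75], axis=2)
    return IQR_TO_SD * (q75 - q25)


def stage_summary(
    noisy: NoisyChannelResult,
    interpolated_fraction: float = 0.0,
    reference_correlation: float = float("nan"),
) -> DatasetSummary:
    """Summary measures from one detection stage's windowed arrays."""
    maxcorr = noisy.stats.max_correlation
    d = noisy.stats.window_deviation
    channel_medians = np.nanmedian(maxcorr, axis=1)
    d_flat = d[np.isfinite(d)]
    med_d = float(np.median(d_flat))
    ratio = float(robust_sd(d_flat) / med_d) if med_d != 0 else float("inf")
    return DatasetSummary(
        mean_max_correlation=float(np.nanmean(maxcorr)),
        median_max_correlation=float(np.nanmedian(channel_medians)),
        mean_median_max_correlation=float(np.nanmean(channel_medians)),
        median_window_deviation=med_d,
        deviation_ratio=ratio,
        interpolated_fraction=float(interpolated_fraction),
        reference_correlation=float(reference_correlation),
    )


def summarize(recording: Recording, result: ReferenceResult) -> DatasetSummary:
    """Dataset summary from the final-stage statistics.

    ``recording`` is the (line-noise-cleaned) input to referencing, used to
    form the ordinary average reference for the comparison correlation.
    """
    if result.noisy_final is None:
        raise ValueError("reference result is missing the final statistics snapshot")
    ordinary = recording.data[recording.eval_indices].mean(axis=0)
    robust = np.asarray(result.reference_signal)
    so, sr = ordinary.std(), robust.std()
    if so > 0 and sr > 0:
        ref_corr = float(np.corrcoef(ordinary, robust)[0, 1])
    else:
        ref_corr = 1.0 if np.allclose(ordinary, robust) else 0.0
    n_ref = len(recording.evaluation_channels)
    return stage_summary(
        result.noisy_final,
        interpolated_fraction=len(result.interpolated) / n_ref,
        reference_correlation=ref_corr,
    )


def _interval_distance(value: float, interval=GOOD_CORRELATION_INTERVAL) -> float:
    lo, hi = interval
    if lo <= value <= hi:
        return 0.0
    return lo - value if value < lo else value - hi


def flag_issues(before: DatasetSummary, after: DatasetSummary) -> IssueFlags:
    """The three issue heuristics comparing pre/post-referencing summaries."""
    d_before = _interval_distance(before.mean_median_max_correlation)
    d_after = _interval_distance(after.mean_median_max_correlation)
    corr_not_improved = d_before > 0 and d_after >= d_before
    corr_too_high = (
        after.mean_max_correlation > MEAN_CORRELATION_CEILING
        and after.median_max_correlation > MEDIAN_CORRELATION_CEILING
    )
    too_many = after.interpolated_fraction > MAX_INTERPOLATED_FRACTION
    return IssueFlags(corr_not_improved, corr_too_high, too_many)


def collection_summary(summaries, flags=None, names=None) -> pd.DataFrame:
    """Per-dataset summary table with a trailing per-collection median row."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("empty collection")
    rows = [asdict(s) for s in summaries]
    index = list(names) if names is not None else list(range(len(summaries)))
    table = pd.DataFrame(rows, index=index)
    if flags is not None:
        table["issues"] = [f.any for f in flags]
    median = table.select_dtypes("number").median()
    median_row = pd.DataFrame([median], index=["median"])
    return pd.concat([table, median_row])


def build_report(
    recording: Recording,
    result: ReferenceResult,
    config_flat: dict | None = None,
) -> dict:
    """Machine-readable report: summaries, flags, bad channels per stage."""
    before = stage_summary(result.noisy_original)
    after = summarize(recording, result)
    flags = flag_issues(before, after)

    def bad_map(noisy):
        return {cat: sorted(chs) for cat, chs in noisy.bad_by.items()}

    report = {
        "summary": asdict(after),
        "summary_original": asdict(before),
        "issues": asdict(flags),
        "interpolated": sorted(result.interpolated),
        "still_bad": sorted(result.still_bad),
        "iterations_used": result.iterations_used,
        "bad_channels": {
            "original": bad_map(result.noisy_original),
            "before_interp": bad_map(result.noisy_before_interp)
            if result.noisy_before_interp else None,
            "final": bad_map(result.noisy_final) if result.noisy_final else None,
        },
    }
    if config_flat is not None:
        report["config"] = {k: v for k, v in config_flat.items()}
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
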