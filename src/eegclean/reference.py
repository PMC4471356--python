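"""Two-phase robust average referencing.

Phase 1 iteratively estimates the per-sample mean the recording would have if
no channels were bad: reference against a robust initial estimate (channelwise
median), detect bad channels, interpolate them, and recompute the mean until
the accumulated bad set stops changing.  Phase 2 references the data by that
estimate, detects bad channels afresh ("channel forgetting"), interpolates
them, and applies a final mean correction so the output is exactly zero-mean
across the reference channels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interpolation import interpolate_channels
from .model import Recording
from .noisy import NoisyChannelResult, find_noisy_channels
from .params import NoisyChannelParams, ReferenceParams

__all__ = ["ReferenceResult", "ReferenceError", "perform_reference",
           "phase1_estimate_true_mean", "phase2_final_reference"]


class ReferenceError(RuntimeError):
    """Raised when a meaningful robust reference cannot be computed."""


@dataclass
class ReferenceResult:
    reference_signal: np.ndarray
    interpolated: frozenset
    still_bad: frozenset
    noisy_original: NoisyChannelResult
    noisy_before_interp: NoisyChannelResult | None
    noisy_final: NoisyChannelResult | None
    iterations_used: int
    original_bad_signals: dict = field(default_factory=dict)  # label -> raw row


def _eval_mean(recording: Recording) -> np.ndarray:
    return recording.data[recording.eval_indices].mean(axis=0)


def _check_bad_budget(bad, recording: Recording, params: ReferenceParams):
    n_eval = len(recording.evaluation_channels)
    if len(bad) > params.max_bad_fraction * n_eval:
        raise ReferenceError(
            f"{len(bad)} of {n_eval} evaluation channels flagged bad; a robust "
            "reference would be meaningless"
        )


def phase1_estimate_true_mean(
    recording: Recording,
    params: ReferenceParams | None = None,
    noisy_params: NoisyChannelParams | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Iterative true-mean estimation.

    Returns ``(reference_signal, bad_channels, unusable, first_pass_result,
    iterations)``; the first detection pass doubles as the 'original'
    statistics snapshot.
    """
    params = params or ReferenceParams()
    noisy_params = noisy_params or NoisyChannelParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eidx = recording.eval_indices
    if params.initial_estimate == "median":
        estimate = np.median(recording.data[eidx], axis=0)
    elif params.initial_estimate == "mean":
        estimate = recording.data[eidx].mean(axis=0)
    else:
        raise ValueError(f"unknown initial estimate {params.initial_estimate!r}")

    bad: set = set()
    unusable: set = set()
    first_pass: NoisyChannelResult | None = None
    iterations = 0
    reference_signal = None
    for iterations in range(1, params.max_iterations + 1):
        temp = recording.with_data(recording.data - estimate)
        result = find_noisy_channels(temp, noisy_params, rng)
        if first_pass is None:
            first_pass = result
        unusable |= set(result.unusable)
        new_bad = set(result.all_bad)
        if new_bad <= bad:
            break
        bad |= new_bad
        _check_bad_budget(bad, recording, params)
        interpolated = interpolate_channels(recording, bad)
        estimate = _eval_mean(interpolated)
        reference_signal = estimate
    if reference_signal is None:  # no bad channels ever accumulated
        if bad:
            reference_signal = _eval_mean(interpolate_channels(recording, bad))
        else:
            reference_signal = _eval_mean(recording)
    return reference_signal, frozenset(bad), frozenset(unusable), first_pass, iterations


def phase2_final_reference(
    recording: Recording,
    reference_signal: np.ndarray,
    unusable: frozenset = frozenset(),
    params: ReferenceParams | None = None,
    noisy_params: NoisyChannelParams | None = None,
    rng: np.random.Generator | int | None = None,
):
    """Reference by the phase-1 estimate, detect afresh, interpolate, correct.

    Returns ``(referenced_recording, interpolated_set, before_interp_result,
    final_reference_signal)``.
    """
    params = params or ReferenceParams()
    noisy_params = noisy_params or NoisyChannelParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    referenced = recording.with_data(recording.data - reference_signal)
    # unusable channels are interpolated up front and removed from
    # consideration: detection never re-tests them
    if unusable:
        detect_input = interpolate_channels(referenced, unusable)
        detect_input.evaluation_channels = tuple(
            l for l in referenced.evaluation_channels if l not in unusable
        )
    else:
        detect_input = referenced
    result = find_noisy_channels(detect_input, noisy_params, rng)
    bad = frozenset(result.all_bad) | unusable
    _check_bad_budget(bad, recording, params)
    final = interpolate_channels(referenced, bad) if bad else referenced
    correction = _eval_mean(final)
    final = final.with_data(final.data - correction)
    return final, bad, result, np.asarray(reference_signal) + correction


def perform_reference(
    recording: Recording,
    params: ReferenceParams | None = None,
    noisy_params: NoisyChannelParams | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[Recording, ReferenceResult]:
    """Full robust average referencing with three-stage statistics snapshots."""
    params = params or ReferenceParams()
    noisy_params = noisy_params or NoisyChannelParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ref_signal, _phase1_bad, unusable, first_pass, iterations = (
        phase1_estimate_true_mean(recording, params, noisy_params, rng)
    )
    referenced, interpolated, before_interp, ref_signal = phase2_final_reference(
        recording, ref_signal, unusable, params, noisy_params, rng
    )
    final_input = referenced
    if unusable:
        final_input = referenced.copy()
        final_input.evaluation_channels = tuple(
            l for l in referenced.evaluation_channels if l not in unusable
        )
    final_result = find_noisy_channels(final_input, noisy_params, rng)
    originals = {
        label: recording.data[recording.montage.index(label)].copy()
        for label in sorted(interpolated)
    }
    result = ReferenceResult(
        reference_signal=ref_signal,
        interpolated=interpolated,
        still_bad=frozenset(final_result.all_bad),
        noisy_original=first_pass,
        noisy_before_interp=before_interp,
        noisy_final=final_result,
        iterations_used=iterations,
        original_bad_signals=originals,
    )
    return referenced, result
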