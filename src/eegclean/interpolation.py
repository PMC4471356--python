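"""Spherical-spline scalp interpolation (Perrin-style Legendre kernel).

Used both to replace bad channels and as the predictor inside the RANSAC
criterion.  The kernel is g(x) = (1/4pi) sum_{n=1..L} (2n+1)/(n (n+1))^m P_n(x)
with stiffness m = 4 and Legendre truncation L = 7; the linear system includes
a constant term so constant fields are reproduced exactly, and a small
diagonal loading stabilizes near-coincident electrodes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

from .model import Montage, Recording

__all__ = [
    "SplineModel",
    "spline_kernel",
    "build_interpolation_matrix",
    "interpolate_channels",
]

DEFAULT_ORDER = 4
DEFAULT_MAX_DEGREE = 7
DEFAULT_REGULARIZATION = 1e-5


def _kernel_coefficients(m: int, max_degree: int) -> np.ndarray:
    n = np.arange(1, max_degree + 1, dtype=np.float64)
    coeffs = np.zeros(max_degree + 1)
    coeffs[1:] = (2 * n + 1) / (n**m * (n + 1) ** m) / (4 * np.pi)
    return coeffs


def spline_kernel(
    cos_angle, m: int = DEFAULT_ORDER, max_degree: int = DEFAULT_MAX_DEGREE
):
    """Evaluate the Legendre-series kernel at cos(angular distance)."""
    x = np.asarray(cos_angle, dtype=np.float64)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("cos_angle outside [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    out = npleg.legval(x, _kernel_coefficients(m, max_degree))
    return float(out) if np.isscalar(cos_angle) else out


def _unit(positions: np.ndarray) -> np.ndarray:
    pos = np.asarray(positions, dtype=np.float64)
    norms = np.linalg.norm(pos, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm electrode position")
    return pos / norms


@dataclass(frozen=True)
class SplineModel:
    source_positions: np.ndarray
    target_positions: np.ndarray
    m: int = DEFAULT_ORDER
    max_degree: int = DEFAULT_MAX_DEGREE
    regularization: float = DEFAULT_REGULARIZATION

    def __post_init__(self):
        object.__setattr__(self, "source_positions", _unit(self.source_positions))
        object.__setattr__(self, "target_positions", _unit(self.target_positions))


def build_interpolation_matrix(model: SplineModel) -> np.ndarray:
    """Targets x sources weight matrix mapping source signals to estimates.

    Solves [[G + lam*I, 1], [1^T, 0]] [c; d] = [v; 0] for every unit source
    vector v at once, then evaluates c and d at the target positions.
    """
    src = model.source_positions
    tgt = model.target_positions
    ns = src.shape[0]
    if ns < 3:
        raise ValueError(f"need at least 3 source channels, got {ns}")
    g_ss = spline_kernel(src @ src.T, model.m, model.max_degree)
    g_ts = spline_kernel(tgt @ src.T, model.m, model.max_degree)
    a = np.zeros((ns + 1, ns + 1))
    # loading is scaled by the kernel diagonal so its effect is unit-free
    lam = model.regularization * float(np.mean(np.diag(g_ss)))
    a[:ns, :ns] = g_ss + lam * np.eye(ns)
    a[:ns, ns] = 1.0
    a[ns, :ns] = 1.0
    b = np.zeros((ns + 1, ns))
    b[:ns, :ns] = np.eye(ns)
    try:
        x = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular spline system; coincident electrode positions?"
        ) from exc
    return np.hstack([g_ts, np.ones((tgt.shape[0], 1))]) @ x


def interpolate_channels(recording: Recording, bad, *, keep_montage_order=True) -> Recording:
    """Replace ``bad`` channels with spherical-spline estimates.

    Sources are the evaluation channels not in ``bad``; all other rows are
    untouched bit-wise.  Callers wanting the originals back must keep them
    (the reference stage records them in its result).
    """
    bad = sorted(set(bad))
    if not bad:
        return recording.copy()
    unknown = set(bad) - set(recording.montage.labels)
    if unknown:
        raise KeyError(f"bad channels not in montage: {sorted(unknown)}")
    good = [l for l in recording.evaluation_channels if l not in set(bad)]
    if len(good) < 3:
        raise ValueError(
            f"only {len(good)} good channels remain; need at least 3 to interpolate"
        )
    montage = recording.montage.normalized()
    good_idx = montage.indices(good)
    bad_idx = montage.indices(bad)
    model = SplineModel(montage.positions[good_idx], montage.positions[bad_idx])
    weights = build_interpolation_matrix(model)
    data = recording.data.copy()
    data[bad_idx] = weights @ data[good_idx]
    return recording.with_data(data)
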