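"""Bundled idealized electrode layouts on the unit sphere.

Coordinates use x = right, y = anterior, z = superior.  Each electrode is
specified by its polar angle from the vertex and its azimuth from the nose
(positive toward the left ear), which reproduces the familiar extended 10-20
geometry closely enough for interpolation and synthesis work.
"""
from __future__ import annotations

import numpy as np

from .model import Montage

__all__ = ["standard_cap_32"]

# label, polar angle from vertex (deg), azimuth from nose (deg, +left)
_CAP_32 = [
    ("Cz", 0.0, 0.0),
    ("FCz", 22.5, 0.0),
    ("CPz", 22.5, 180.0),
    ("Fz", 45.0, 0.0),
    ("Pz", 45.0, 180.0),
    ("C3", 45.0, 90.0),
    ("C4", 45.0, -90.0),
    ("FC3", 52.0, 55.0),
    ("FC4", 52.0, -55.0),
    ("CP3", 52.0, 125.0),
    ("CP4", 52.0, -125.0),
    ("F3", 60.0, 28.0),
    ("F4", 60.0, -28.0),
    ("P3", 60.0, 152.0),
    ("P4", 60.0, -152.0),
    ("POz", 67.5, 180.0),
    ("FT7", 75.0, 72.0),
    ("FT8", 75.0, -72.0),
    ("TP7", 75.0, 108.0),
    ("TP8", 75.0, -108.0),
    ("Fpz", 90.0, 0.0),
    ("Fp1", 90.0, 18.0),
    ("Fp2", 90.0, -18.0),
    ("F7", 90.0, 54.0),
    ("F8", 90.0, -54.0),
    ("T7", 90.0, 90.0),
    ("T8", 90.0, -90.0),
    ("P7", 90.0, 126.0),
    ("P8", 90.0, -126.0),
    ("O1", 90.0, 162.0),
    ("O2", 90.0, -162.0),
    ("Oz", 90.0, 180.0),
]


def _to_cartesian(polar_deg: float, azimuth_deg: float) -> tuple[float, float, float]:
    th = np.deg2rad(polar_deg)
    az = np.deg2rad(azimuth_deg)
    return (-np.sin(th) * np.sin(az), np.sin(th) * np.cos(az), np.cos(th))


def standard_cap_32() -> Montage:
    """32 scalp positions on the unit sphere with 10-20-style labels."""
    labels = tuple(row[0] for row in _CAP_32)
    positions = np.array([_to_cartesian(t, a) for _, t, a in _CAP_32])
    return Montage(labels, positions)
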