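"""Axial (180°-periodic) angle arithmetic used throughout the package.

Orientations of line-like structures are directionless: theta and
theta + 180° describe the same strut axis.  All angles are degrees,
counter-clockwise from the +x axis (x = columns increasing rightward,
y = rows increasing *upward* in the mathematical sense, i.e. the
angle of a pixel displacement (drow, dcol) is atan2(-drow, dcol)).
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_axial", "axial_difference", "axial_mean"]


def wrap_axial(theta):
    """Wrap angle(s) into [0, 180)."""
    out = np.mod(theta, 180.0)
    # float rounding of tiny negatives can land exactly on 180
    return np.where(out >= 180.0, 0.0, out)[()]


def axial_difference(a, b):
    """Minimal absolute difference between two axial angles, in [0, 90]."""
    d = np.mod(np.asarray(a, dtype=float) - b, 180.0)
    return np.minimum(d, 180.0 - d)


def axial_mean(theta, weights=None):
    """Weighted axial mean via the doubled-angle circular mean, in [0, 180)."""
    t = np.deg2rad(2.0 * np.asarray(theta, dtype=float))
    if weights is None:
        c, s = np.mean(np.cos(t)), np.mean(np.sin(t))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        c, s = np.sum(w * np.cos(t)), np.sum(w * np.sin(t))
    return wrap_axial(np.rad2deg(np.arctan2(s, c)) / 2.0)
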