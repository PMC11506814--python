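"""Axial (orientation) angle helpers.

Orientations are measured from the vertical axis, in radians, on the axial
domain (-pi/2, pi/2]: an orientation theta and theta + pi describe the same
dipole axis. Full-circle motion directions use (-pi, pi].
"""
from __future__ import annotations

import numpy as np

HALF_PI = np.pi / 2.0


def wrap_axial(theta):
    """Wrap angles onto the axial domain (-pi/2, pi/2]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = (theta + HALF_PI) % np.pi - HALF_PI
    # map the open endpoint -pi/2 to +pi/2 so the domain is (-pi/2, pi/2]
    wrapped = np.where(wrapped == -HALF_PI, HALF_PI, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def wrap_direction(theta):
    """Wrap angles onto (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = (theta + np.pi) % (2 * np.pi) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def axial_mean_sd(theta: np.ndarray) -> tuple[float, float]:
    """Circular mean and SD of axial data via angle doubling.

    For a wrapped normal the circular SD sqrt(-2 ln R)/2 of the doubled
    angles recovers the generating sigma exactly in expectation.
    """
    z = np.exp(2j * np.asarray(theta, dtype=float))
    m = z.mean()
    r = np.abs(m)
    mean = wrap_axial(np.angle(m) / 2.0)
    sd = np.sqrt(-2.0 * np.log(r)) / 2.0 if r > 0 else np.inf
    return float(mean), float(sd)


def axial_resultant_length(theta: np.ndarray) -> float:
    """Mean resultant length of doubled angles; ~0 for uniform axial data."""
    return float(np.abs(np.exp(2j * np.asarray(theta, dtype=float)).mean()))
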