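"""Circular (angular) arithmetic in degrees.

All angles in this package are stored in degrees on [0, 360); trigonometric
conversion to radians happens only at the network boundary and inside the
von Mises likelihoods. Signed circular differences lie in (-180, 180].
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "signed_diff_deg", "circular_error", "circular_mean_deg"]


def wrap_deg(angle):
    """Reduce an angle (scalar or array) to [0, 360)."""
    return np.mod(angle, 360.0)


def signed_diff_deg(a, b):
    """Signed circular difference a - b in (-180, 180] degrees."""
    d = np.mod(np.asarray(a, dtype=float) - np.asarray(b, dtype=float), 360.0)
    out = np.where(d > 180.0, d - 360.0, d)
    return out if out.ndim else float(out)


def circular_error(response, truth):
    """Absolute circular distance in [0, 180] degrees."""
    d = np.abs(np.mod(np.asarray(response, dtype=float) - np.asarray(truth, dtype=float), 360.0))
    out = np.minimum(d, 360.0 - d)
    return out if out.ndim else float(out)


def circular_mean_deg(angles_deg):
    """Circular mean direction of a sample, in [0, 360)."""
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(wrap_deg(np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean()))))
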