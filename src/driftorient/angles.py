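"""Shared angle conventions.

All public angles are degrees in [0, 360), measured clockwise from north
(0 = north, 90 = east). Internally trigonometry is done in radians on the
(sin, cos) = (east, north) unit-vector convention, so ``atan2(sin, cos)``
returns a compass angle directly.
"""

from __future__ import annotations

import enum

import numpy as np


class Frame(str, enum.Enum):
    """Reference frame an angle series is expressed in."""

    MAGNETIC_NORTH = "magnetic_north"
    TRUE_NORTH = "true_north"
    MOON_RELATIVE = "moon_relative"
    SUN_RELATIVE = "sun_relative"
    CAMERA = "camera"


def wrap_deg(angle):
    """Wrap angle(s) in degrees into [0, 360).

    The single shared wrapping utility: every module routes degree
    wrapping through here so the half-open convention is uniform.
    """
    wrapped = np.mod(angle, 360.0)
    # np.mod can return 360.0 for tiny negative inputs due to rounding
    wrapped = np.where(wrapped >= 360.0, wrapped - 360.0, wrapped)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return np.asarray(wrapped, dtype=float)


def wrap_signed_deg(angle):
    """Wrap angle(s) in degrees into (-180, 180]."""
    wrapped = np.mod(np.negative(angle) + 180.0, 360.0)
    out = 180.0 - wrapped
    if np.ndim(angle) == 0:
        return float(out)
    return np.asarray(out, dtype=float)


def to_unit_vectors(angles_deg):
    """Return (east, north) components of unit vectors for compass angles."""
    rad = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return np.sin(rad), np.cos(rad)


def from_components(east, north):
    """Compass angle in [0, 360) from (east, north) components."""
    return wrap_deg(np.rad2deg(np.arctan2(east, north)))
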