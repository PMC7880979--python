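"""Gaze geometry: Fick-angle eye orientations and screen cm/degree conversions.

Some eye trackers always filter the gaze point they report in screen
coordinates but also expose a raw 3-D gaze direction vector.  Decomposing
that vector into Fick angles (a horizontal rotation about the vertical axis
followed by a vertical rotation about the once-rotated horizontal axis)
recovers an angular eye-orientation trace that has bypassed the position
filter, which is what the spectral analysis needs.

Coordinate convention used throughout: x right, y up, z forward (out of the
head toward the screen).  Straight-ahead gaze is (0, 0, 1) and maps to Fick
angles (0, 0).  Torsion is not represented: a gaze direction only determines
the two angles.  Sign conventions differ between vendor headbox frames; the
power-spectrum slope is invariant to sign flips, so the choice here is purely
a documentation matter.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError, InvalidConfigError

__all__ = ["fick_from_vector", "vector_from_fick", "cm_to_deg", "deg_to_cm"]


def fick_from_vector(v):
    """Decompose gaze direction vector(s) into Fick angles in degrees.

    Parameters
    ----------
    v : array_like, shape (3,) or (n, 3)
        Gaze direction(s); need not be normalized (the decomposition is
        scale invariant) but must be nonzero with a positive forward (z)
        component.

    Returns
    -------
    theta_deg, phi_deg : float or ndarray
        Horizontal (azimuth) and vertical (elevation) Fick angles.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    v2 = np.atleast_2d(v)
    if v2.shape[-1] != 3:
        raise DomainError("gaze vectors must have 3 components")
    norms = np.linalg.norm(v2, axis=-1)
    if np.any(norms == 0):
        raise DomainError("zero gaze vector has no orientation")
    if np.any(v2[:, 2] <= 0):
        raise DomainError("gaze vector must point into the forward hemisphere (z > 0)")
    theta = np.degrees(np.arctan2(v2[:, 0], v2[:, 2]))
    phi = np.degrees(np.arctan2(v2[:, 1], np.hypot(v2[:, 0], v2[:, 2])))
    if single:
        return float(theta[0]), float(phi[0])
    return theta, phi


def vector_from_fick(theta_deg, phi_deg):
    """Unit gaze direction(s) for Fick angles in degrees.

    Inverse of :func:`fick_from_vector`; round-trips to ~1e-9 degrees over
    the forward hemisphere.
    """
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    phi = np.radians(np.asarray(phi_deg, dtype=float))
    x = np.cos(phi) * np.sin(theta)
    y = np.sin(phi)
    z = np.cos(phi) * np.cos(theta)
    out = np.stack([x, y, z], axis=-1)
    return out


def cm_to_deg(offset_cm, viewing_distance_cm):
    """Convert a screen offset in cm to degrees of visual angle.

    deg = atan(offset / distance) * 180 / pi.  Odd in the offset.
    """
    if viewing_distance_cm <= 0:
        raise InvalidConfigError("viewing_distance_cm must be positive")
    return np.degrees(np.arctan2(np.asarray(offset_cm, dtype=float), viewing_distance_cm))


def deg_to_cm(angle_deg, viewing_distance_cm):
    """Inverse of :func:`cm_to_deg` (valid for |angle| < 90 deg)."""
    if viewing_distance_cm <= 0:
        raise InvalidConfigError("viewing_distance_cm must be positive")
    return np.tan(np.radians(np.asarray(angle_deg, dtype=float))) * viewing_distance_cm
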