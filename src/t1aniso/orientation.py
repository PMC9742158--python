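"""Fibre-to-field angle maps and the Watson kappa <-> ODI correspondence."""

from __future__ import annotations

import numpy as np

__all__ = [
    "fibre_to_field_angle",
    "angle_map",
    "odi_from_kappa",
    "kappa_from_odi",
]

DEFAULT_B0_AXIS = np.array([0.0, 0.0, 1.0])


def fibre_to_field_angle(v1, b0_axis=DEFAULT_B0_AXIS):
    """Angle (degrees, in [0, 90]) between a fibre axis and the main field.

    ``theta = arccos(|v1 . b0|) * 180 / pi``.  Invariant to the sign of
    ``v1`` (axes, not vectors).  Accepts a single 3-vector or an
    ``(..., 3)`` array; zero-length vectors map to NaN.
    """
    v1 = np.asarray(v1, dtype=float)
    b0 = np.asarray(b0_axis, dtype=float)
    nb = np.linalg.norm(b0)
    if b0.shape != (3,) or nb == 0:
        raise ValueError("b0_axis must be a nonzero 3-vector")
    b0 = b0 / nb
    norms = np.linalg.norm(v1, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(v1 @ b0) / norms
    theta = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    theta = np.where(norms > 0, theta, np.nan)
    if theta.ndim == 0:
        return float(theta)
    return theta


def angle_map(v1_volume, mask=None, b0_axis=DEFAULT_B0_AXIS):
    """Per-voxel fibre-to-field angle from a ``(..., 3)`` V1 volume.

    Voxels outside ``mask`` (or with zero V1) are NaN.
    """
    theta = fibre_to_field_angle(v1_volume, b0_axis)
    if mask is not None:
        theta = np.where(np.asarray(mask, dtype=bool), theta, np.nan)
    return theta


def odi_from_kappa(kappa):
    """Orientation dispersion index ``(2/pi) * arctan(1/kappa)``.

    Strictly decreasing bijection from [0, inf) onto (0, 1]; ``kappa = 0``
    maps to ODI = 1 (fully dispersed).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    with np.errstate(divide="ignore"):
        odi = (2.0 / np.pi) * np.arctan2(1.0, kappa)
    if odi.ndim == 0:
        return float(odi)
    return odi


def kappa_from_odi(odi):
    """Inverse of :func:`odi_from_kappa`; rejects ODI outside (0, 1]."""
    odi = np.asarray(odi, dtype=float)
    if np.any(odi <= 0) or np.any(odi > 1):
        raise ValueError("ODI must lie in (0, 1]")
    kappa = 1.0 / np.tan(np.pi * odi / 2.0)
    kappa = np.where(odi == 1.0, 0.0, kappa)
    if kappa.ndim == 0:
        return float(kappa)
    return kappa
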