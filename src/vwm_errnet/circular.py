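"""Circular-statistics primitives for analog-report errors.

Analog-report tasks probe memory of a feature that lives on a circle:
orientation is 180°-periodic, location on a ring is 360°-periodic. Both are
mapped to a common transformed circle where ±90° corresponds to ±π radians
(equivalently ±1 in "πrad" units), so a single von Mises machinery serves
both tasks. All internal angles are radians on that transformed circle.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import i0e, i1e

__all__ = [
    "wrap_angle",
    "deg_to_pirad",
    "pirad_to_rad",
    "response_error_pirad",
    "HemifieldSwapError",
    "bessel_ratio",
    "inv_bessel_ratio",
    "kappa_to_sigma",
    "sigma_to_kappa",
]

#: concentration ceiling; beyond this the von Mises is numerically a point mass
KAPPA_MAX = 1e4


class HemifieldSwapError(ValueError):
    """Raised when a location response falls in the uncued hemifield (|error| > 90°)."""

    def __init__(self, n_swaps: int):
        self.n_swaps = int(n_swaps)
        super().__init__(
            f"{n_swaps} location trial(s) with |error| > 90 deg (uncued-hemifield "
            "response); such trials are rejected from the analysis"
        )


def wrap_angle(theta, period: float = 2.0 * np.pi):
    """Wrap angles into the half-open interval ``(-period/2, period/2]``."""
    theta = np.asarray(theta, dtype=float)
    half = period / 2.0
    wrapped = np.mod(-theta + half, period)
    out = -(wrapped - half)
    return out if out.ndim else float(out)


def deg_to_pirad(deg):
    """Map degrees to πrad units (±90° -> ±1)."""
    return np.asarray(deg, dtype=float) / 90.0


def pirad_to_rad(x):
    """πrad units to radians on the transformed circle (±1 -> ±π)."""
    return np.asarray(x, dtype=float) * np.pi


def response_error_pirad(target_deg, response_deg, task: str):
    """Minimal signed circular response error in πrad units, ``(-1, 1]``.

    Parameters
    ----------
    target_deg, response_deg : array-like
        Feature values in degrees. Orientations are interpreted on a
        180°-periodic space; locations on a 360°-periodic space.
    task : {"orientation", "location"}

    Returns
    -------
    ndarray or float
        Signed error, ``(response - target)`` wrapped minimally, divided by 90.

    Raises
    ------
    HemifieldSwapError
        For location trials with |error| > 90°: responses in the uncued
        hemifield are not part of the response model and are rejected (with
        a count) rather than folded.
    """
    target = np.asarray(target_deg, dtype=float)
    response = np.asarray(response_deg, dtype=float)
    if not (np.all(np.isfinite(target)) and np.all(np.isfinite(response))):
        raise ValueError("target and response must be finite")
    if task == "orientation":
        err = wrap_angle(response - target, period=180.0)
    elif task == "location":
        err = wrap_angle(response - target, period=360.0)
        n_swaps = np.sum(np.abs(err) > 90.0)
        if n_swaps:
            raise HemifieldSwapError(n_swaps)
    else:
        raise ValueError(f"unknown task {task!r}")
    return deg_to_pirad(err)


def bessel_ratio(kappa):
    """A(κ) = I₁(κ)/I₀(κ), the mean resultant length of a von Mises(κ)."""
    kappa = np.asarray(kappa, dtype=float)
    out = i1e(kappa) / i0e(kappa)
    return out if out.ndim else float(out)


def inv_bessel_ratio(r: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Invert A(κ) = r by Newton iteration from the Banerjee closed-form start.

    Returns 0 for r <= 0 and ``KAPPA_MAX`` for r at (or numerically beyond) 1.
    """
    if not np.isfinite(r):
        raise ValueError("resultant length must be finite")
    if r <= 0.0:
        return 0.0
    r = min(r, 1.0 - 1e-12)
    kappa = r * (2.0 - r * r) / (1.0 - r * r)  # Banerjee et al. start
    kappa = min(max(kappa, 1e-8), KAPPA_MAX)
    for _ in range(max_iter):
        a = bessel_ratio(kappa)
        # A'(κ) = 1 - A/κ - A²
        da = 1.0 - a / kappa - a * a if kappa > 1e-8 else 0.5
        if da <= 0:
            break
        step = (a - r) / da
        kappa = min(max(kappa - step, 1e-8), KAPPA_MAX)
        if abs(step) < tol:
            break
    return kappa


def kappa_to_sigma(kappa):
    """Circular standard deviation σ_vM = sqrt(-2 ln A(κ)).

    Units are radians on the transformed circle (where ±90° of stimulus
    space spans ±π), matching the scale on which group means are reported.
    κ = 0 gives +inf with a warning (precision undefined for a uniform
    response distribution).
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be >= 0")
    if np.any(kappa == 0):
        warnings.warn("kappa = 0: circular SD undefined (uniform), returning inf")
    with np.errstate(divide="ignore"):
        out = np.sqrt(-2.0 * np.log(bessel_ratio(kappa)))
    return out if out.ndim else float(out)


def sigma_to_kappa(sigma):
    """Inverse of :func:`kappa_to_sigma` (σ in transformed-circle radians)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    flat = np.atleast_1d(sigma)
    out = np.array([inv_bessel_ratio(float(np.exp(-s * s / 2.0))) for s in flat])
    return out.reshape(sigma.shape) if sigma.ndim else float(out[0])
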