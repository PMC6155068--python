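"""Closed-form optics of the planarian two-eye light-input model.

A planarian eye is a pigment-cup ocellus: the semilunar pigment cup shades
the photoreceptors from one side, so each eye's input is well approximated
by the sine of the angle between the incoming light and the eye's shading
plane. The two eyes are mounted obliquely (each rotated by ``bf/2`` toward
the midline), which creates an anterior *binocular field* of width ``bf``
where both eyes are illuminated, and a posterior blind field where neither
is.

With the light bearing ``theta`` measured from the anterior body axis
(positive to the animal's right) the per-eye inputs are

    L(theta) = max(0, -sin(theta - bf/2))
    R(theta) = max(0,  sin(theta + bf/2))

both clamped to [0, 1] (maximum input 1.0).  The signed difference
``R - L`` is the quantity the animal thresholds when deciding to turn.
All interfaces are in degrees; radians appear only inside trig calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "EyeGeometry",
    "InputPair",
    "wrap180",
    "wrap360",
    "eye_inputs",
    "input_difference",
    "max_attainable_difference",
    "front_blind_half_angle",
    "response_band",
    "posterior_blind_field",
]


def wrap180(angle_deg):
    """Normalize an angle (degrees) into (-180, 180].

    Accepts scalars or arrays; the wrapped value keeps the input's shape.
    """
    a = np.asarray(angle_deg, dtype=float)
    r = np.mod(a, 360.0)
    r = np.where(r > 180.0, r - 360.0, r)
    return float(r) if np.ndim(angle_deg) == 0 else r


def wrap360(angle_deg):
    """Normalize an angle (degrees) into [0, 360)."""
    a = np.asarray(angle_deg, dtype=float)
    r = np.mod(a, 360.0)
    return float(r) if np.ndim(angle_deg) == 0 else r


@dataclass(frozen=True)
class EyeGeometry:
    """Eye-placement parameters.

    Parameters
    ----------
    binocular_field : float
        Width ``bf`` of the anterior binocular field in degrees,
        ``0 <= bf < 180``.  Approximately 40 for *Dugesia japonica*,
        60 for *Schmidtea mediterranea*.
    monocular_field : float, optional
        Measured monocular visual field ``alpha`` in degrees (morphometric
        only; the sine model implicitly assumes 180).  Must satisfy
        ``90 < alpha <= 180`` when given.
    """

    binocular_field: float = 40.0
    monocular_field: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.binocular_field < 180.0:
            raise ValueError(
                f"binocular_field must be in [0, 180), got {self.binocular_field}"
            )
        if self.monocular_field is not None and not 90.0 < self.monocular_field <= 180.0:
            raise ValueError(
                f"monocular_field must be in (90, 180], got {self.monocular_field}"
            )

    @property
    def obliqueness(self) -> float:
        """Per-eye obliqueness ``beta = bf/2`` in degrees."""
        return self.binocular_field / 2.0


class InputPair(NamedTuple):
    """Dimensionless per-eye light inputs, each clamped to [0, 1]."""

    left: float
    right: float


def eye_inputs(theta_deg, geom: EyeGeometry) -> InputPair:
    """Clamped-sine light inputs of the left and right eye.

    ``theta_deg`` is the light bearing relative to the anterior axis in
    degrees (scalar or array).  Mirror symmetry holds exactly:
    ``eye_inputs(-theta)`` swaps left and right.
    """
    theta = np.radians(np.asarray(wrap180(theta_deg), dtype=float))
    beta = math.radians(geom.obliqueness)
    left = np.maximum(0.0, -np.sin(theta - beta))
    right = np.maximum(0.0, np.sin(theta + beta))
    if np.ndim(theta_deg) == 0:
        return InputPair(float(left), float(right))
    return InputPair(left, right)


def input_difference(theta_deg, geom: EyeGeometry):
    """Signed input difference ``R(theta) - L(theta)``.

    Odd in ``theta``; callers take the absolute value for threshold tests.
    """
    left, right = eye_inputs(theta_deg, geom)
    return right - left


def max_attainable_difference(geom: EyeGeometry) -> float:
    """Largest |R - L| over all light bearings.

    1.0 for ``bf <= 90`` (the right eye alone can saturate while the left
    is shaded); ``sin(bf)`` beyond that, where the monocular zones shrink.
    """
    bf = geom.binocular_field
    if bf <= 90.0:
        return 1.0
    return math.sin(math.radians(bf))


def _asin_deg(x: float) -> float:
    return math.degrees(math.asin(x))


def front_blind_half_angle(geom: EyeGeometry, tau: float = 0.5) -> float:
    """Half-angle of the anterior blind-like spot, in degrees.

    The smallest positive bearing at which ``|R - L|`` reaches the response
    threshold ``tau``; light from within ``(-result, +result)`` cannot be
    lateralized.  Inside the binocular zone (``theta <= bf/2``) the
    difference is ``2 cos(bf/2) sin(theta)``; past it, ``sin(theta + bf/2)``.

    Raises ``ValueError`` if no bearing attains ``tau``.
    """
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    if tau > max_attainable_difference(geom):
        raise ValueError(
            f"threshold {tau} exceeds the maximum attainable input "
            f"difference for bf={geom.binocular_field}"
        )
    bf = geom.binocular_field
    beta = geom.obliqueness
    if _asin_deg(tau) >= bf:
        # threshold first crossed in the right-eye-only (monocular) zone
        return _asin_deg(tau) - beta
    return _asin_deg(tau / (2.0 * math.cos(math.radians(beta))))


def response_band(geom: EyeGeometry, tau: float = 0.5) -> tuple[float, float]:
    """Contiguous interval of positive bearings with ``|R - L| > tau``.

    Returns ``(theta_low, theta_high)`` in degrees; by mirror symmetry the
    band ``(-theta_high, -theta_low)`` responds on the other side.  The
    upper edge is ``180 - asin(tau) - bf/2``, where the right-eye input
    falls back through the threshold on its way into the posterior blind
    field.
    """
    low = front_blind_half_angle(geom, tau)
    high = 180.0 - _asin_deg(tau) - geom.obliqueness
    return (low, high)


def posterior_blind_field(geom: EyeGeometry) -> float:
    """Morphometric posterior blind-field width ``2(180 - alpha + beta)``.

    Uses the measured monocular field ``alpha``; independent of the sine
    model (which assumes alpha = 180).  Raises ``ValueError`` when the
    geometry carries no monocular-field measurement.
    """
    if geom.monocular_field is None:
        raise ValueError("posterior_blind_field requires monocular_field (alpha)")
    return 2.0 * (180.0 - geom.monocular_field + geom.obliqueness)
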