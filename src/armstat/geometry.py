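"""Planar two-segment arm geometry and characteristic angles.

The arm is modelled as two rigid segments in a horizontal plane: a proximal
(shoulder) segment of length ``L_s`` and a distal (elbow) segment of length
``L_e``.  The shoulder joint axis is the origin; joint angles are measured
counter-clockwise, the shoulder angle ``alpha_s`` from the X-axis and the
elbow angle ``alpha_e`` from the prolongation of the proximal segment.  The
hand (with the wrist immobilised) is the end-point at which an isometric
force is applied.

Two direction angles govern the statics of force generation at the
end-point and are therefore called the *characteristic angles*:

* ``gamma_s`` — direction of the line from the shoulder axis to the
  end-point,
* ``gamma_e`` — direction of the line from the elbow axis to the end-point,
  which equals ``alpha_s + alpha_e`` identically.

Together with ``h_s``, the shoulder-axis-to-end-point distance, they fix
the phases and amplitudes of the sinusoidal joint-torque waves computed in
:mod:`armstat.torques`.

Two independent computation routes are provided: the closed-form route
(:func:`characteristic_angles`) valid for any segment lengths, and an
end-point-coordinate route (:func:`characteristic_angles_from_endpoint`)
that reconstructs the angles from ``(x, y)`` alone via the isosceles
triangle shoulder-elbow-hand, valid only for equal segment lengths and the
upper half-plane.  Their agreement on a grid is a strong internal
consistency check and is exercised in the test suite and the ``verify``
CLI command.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DegenerateConfiguration, DomainError, UnequalLengths

__all__ = [
    "ArmGeometry",
    "JointConfiguration",
    "EndPoint",
    "CharacteristicAngles",
    "forward_kinematics",
    "endpoint_distance",
    "characteristic_angles",
    "characteristic_angles_from_endpoint",
]

#: Relative threshold below which the end-point is considered to coincide
#: with the shoulder axis (complete elbow flexion with equal segments).
DEGENERACY_TOL = 1e-9


@dataclass(frozen=True)
class ArmGeometry:
    """Segment lengths of the two-joint arm.

    Lengths are expressed in units of the working-space radius, so the
    default ``L_s = L_e = 0.5`` gives a reach ``R = 1``.
    """

    l_s: float = 0.5
    l_e: float = 0.5

    def __post_init__(self) -> None:
        if self.l_s <= 0 or self.l_e <= 0:
            raise ValueError("segment lengths must be positive")

    @property
    def reach(self) -> float:
        """Working-space radius ``R = L_s + L_e``."""
        return self.l_s + self.l_e

    @property
    def equal_lengths(self) -> bool:
        return math.isclose(self.l_s, self.l_e, rel_tol=0.0, abs_tol=1e-12)


@dataclass(frozen=True)
class JointConfiguration:
    """A shoulder/elbow joint-angle pair ``(alpha_s, alpha_e)`` in radians.

    Valid ranges are ``alpha_s in [0, pi)`` and ``alpha_e in [0, pi]``;
    ``alpha_e = pi`` is the idealised complete elbow flexion.
    """

    alpha_s: float
    alpha_e: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_s < math.pi):
            raise ValueError(f"alpha_s must lie in [0, pi), got {self.alpha_s}")
        if not (0.0 <= self.alpha_e <= math.pi):
            raise ValueError(f"alpha_e must lie in [0, pi], got {self.alpha_e}")


@dataclass(frozen=True)
class EndPoint:
    """Hand position in the shoulder-origin frame (normalised units)."""

    x: float
    y: float

    @property
    def radius(self) -> float:
        return math.hypot(self.x, self.y)


@dataclass(frozen=True)
class CharacteristicAngles:
    """The triple ``(gamma_s, gamma_e, h_s)`` governing the torque waves.

    ``gamma_s`` and ``gamma_e`` are the direction angles (rad, CCW from the
    X-axis) of the shoulder-to-hand and elbow-to-hand lines; ``h_s`` is the
    shoulder-to-hand distance.  ``gamma_e >= gamma_s`` holds throughout the
    working space.
    """

    gamma_s: float
    gamma_e: float
    h_s: float

    @property
    def lag(self) -> float:
        """Phase lag ``gamma_e - gamma_s`` between the torque sinusoids."""
        return self.gamma_e - self.gamma_s


def forward_kinematics(geom: ArmGeometry, joints: JointConfiguration) -> EndPoint:
    """End-point position of the arm.

    ``x = L_s cos(alpha_s) + L_e cos(alpha_s + alpha_e)`` and analogously
    with sines for ``y``.
    """
    a, b = joints.alpha_s, joints.alpha_s + joints.alpha_e
    return EndPoint(
        x=geom.l_s * math.cos(a) + geom.l_e * math.cos(b),
        y=geom.l_s * math.sin(a) + geom.l_e * math.sin(b),
    )


def endpoint_distance(geom: ArmGeometry, joints: JointConfiguration) -> float:
    """Distance ``h_s`` from the shoulder axis to the end-point.

    Computed as the Euclidean norm of the end-point coordinates; for equal
    segment lengths this reduces to ``2 L cos(alpha_e / 2)``.
    """
    return forward_kinematics(geom, joints).radius


def characteristic_angles(
    geom: ArmGeometry, joints: JointConfiguration
) -> CharacteristicAngles:
    """Characteristic angles by the closed-form (arctangent) route.

    ``gamma_e = alpha_s + alpha_e`` exactly.  ``gamma_s`` is the
    quadrant-aware arctangent of the end-point coordinates, unwrapped onto
    the branch continuous in both joint angles: the principal two-argument
    arctangent is shifted by the multiple of ``2 pi`` that brings it within
    half a turn of the anchor ``alpha_s + alpha_e / 2`` (the exact value
    for equal segments, and within ``pi/2`` of the true angle in general,
    since gamma_s always lies between ``alpha_s`` and ``alpha_s +
    alpha_e``).  This keeps gamma_s continuous beyond ``pi``, where a
    principal arctangent would wrap.

    Raises
    ------
    DegenerateConfiguration
        If the end-point coincides with the shoulder axis
        (``h_s <= 1e-9 R``), where gamma_s is undefined.
    """
    ep = forward_kinematics(geom, joints)
    h_s = ep.radius
    if h_s <= DEGENERACY_TOL * geom.reach:
        raise DegenerateConfiguration(
            "end-point at the shoulder axis: gamma_s undefined "
            f"(h_s={h_s:.3e}, alpha_e={joints.alpha_e:.6f})"
        )
    anchor = joints.alpha_s + 0.5 * joints.alpha_e
    raw = math.atan2(ep.y, ep.x)
    gamma_s = raw + 2.0 * math.pi * round((anchor - raw) / (2.0 * math.pi))
    return CharacteristicAngles(
        gamma_s=gamma_s,
        gamma_e=joints.alpha_s + joints.alpha_e,
        h_s=h_s,
    )


def characteristic_angles_from_endpoint(
    endpoint: EndPoint, geom: ArmGeometry
) -> CharacteristicAngles:
    """Characteristic angles reconstructed from end-point coordinates alone.

    Uses the isosceles triangle shoulder-elbow-hand: with equal segment
    lengths ``h_s = 2 L cos(gamma_e - gamma_s)``, so the lag is
    ``arccos(h_s / 2L)`` and ``gamma_s = arccos(x / h_s)``.  The arccos
    route is quadrant-blind, hence restricted to the upper half-plane
    (``y >= 0``); it serves as an independent cross-check of
    :func:`characteristic_angles` on the canonical grid.

    Raises
    ------
    UnequalLengths
        If ``L_s != L_e`` (the isosceles shortcut does not apply).
    DomainError
        If ``y < 0`` or the end-point coincides with the shoulder axis.
    """
    if not geom.equal_lengths:
        raise UnequalLengths(
            f"coordinate route requires L_s == L_e, got {geom.l_s} != {geom.l_e}"
        )
    h_s = endpoint.radius
    if h_s <= DEGENERACY_TOL * geom.reach:
        raise DomainError("end-point at the shoulder axis: gamma_s undefined")
    if endpoint.y < 0:
        raise DomainError(f"coordinate route requires y >= 0, got y={endpoint.y}")
    # Clamp against roundoff at the workspace boundary (h_s == 2L).
    lag = math.acos(min(1.0, h_s / geom.reach))
    gamma_s = math.acos(min(1.0, max(-1.0, endpoint.x / h_s)))
    return CharacteristicAngles(gamma_s=gamma_s, gamma_e=gamma_s + lag, h_s=h_s)
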