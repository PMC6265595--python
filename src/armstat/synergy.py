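"""Flexor-extensor synergy sectors of the force-direction cycle.

As the end-point force direction theta sweeps a full turn, each joint
torque changes sign twice, at the *force singular points* (FSPs)
``theta = gamma_s, gamma_s + pi`` (shoulder) and ``gamma_e, gamma_e + pi``
(elbow).  The four FSPs cut the cycle into four sectors characterised by
the sign pair of the torques:

* both torques the same sign — torques of *coinciding* direction (TCD):
  both joints loaded by muscles of the same function (flexor-flexor or
  extensor-extensor);
* opposite signs — torques of *opposing* direction (TOD): flexor at one
  joint with extensor at the other.

The fractional angular measures of the two classes over a full turn are
the synergy weights

    w_TOD = (gamma_e - gamma_s) / pi,    w_TCD = 1 - w_TOD,

so the opposing-direction weight grows linearly with the torque-phase lag
(= alpha_e / 2 for equal segments), from 0 at a fully extended elbow to
the limiting 0.5 at the idealised complete flexion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import OnBoundary
from .geometry import CharacteristicAngles

__all__ = [
    "Sector",
    "SynergyProfile",
    "force_singular_points",
    "classify_sector",
    "synergy_weights",
    "synergy_profile",
]

TWO_PI = 2.0 * math.pi

#: Angular tolerance within which a force direction counts as sitting on an FSP.
BOUNDARY_TOL = 1e-12

_MUSCLE = {+1: "flexor", -1: "extensor"}


def _wrap(theta: float) -> float:
    """Reduce an angle to [0, 2 pi)."""
    return theta % TWO_PI


@dataclass(frozen=True)
class Sector:
    """A half-open force-direction interval [start, end) of constant torque signs."""

    start: float
    end: float
    label: str  # e.g. "Ms+Me-"
    klass: str  # "TCD" | "TOD"
    shoulder_muscle: str  # "flexor" | "extensor"
    elbow_muscle: str

    @property
    def width(self) -> float:
        return (self.end - self.start) % TWO_PI or (
            TWO_PI if self.end != self.start else 0.0
        )


@dataclass(frozen=True)
class SynergyProfile:
    """Full sector decomposition of one end-point's force cycle."""

    fsp: tuple[float, ...]
    sectors: tuple[Sector, ...]
    w_tcd: float
    w_tod: float
    degenerate: bool  # True when gamma_s == gamma_e (elbow fully extended)


def force_singular_points(ca: CharacteristicAngles) -> tuple[float, ...]:
    """Force directions where a joint torque changes sign.

    Returns ``{gamma_s, gamma_e, gamma_s + pi, gamma_e + pi}`` reduced
    mod 2 pi and sorted.  When the elbow is fully extended the shoulder
    and elbow zeros coincide and only two distinct points remain.
    """
    pts = {
        _wrap(ca.gamma_s),
        _wrap(ca.gamma_e),
        _wrap(ca.gamma_s + math.pi),
        _wrap(ca.gamma_e + math.pi),
    }
    # Collapse pairs separated by less than the boundary tolerance
    # (numerically coincident zeros at alpha_e ~ 0).
    out: list[float] = []
    for p in sorted(pts):
        if not out or p - out[-1] > BOUNDARY_TOL:
            out.append(p)
    return tuple(out)


def _signs_at(ca: CharacteristicAngles, theta: float) -> tuple[int, int]:
    s_s = math.sin(theta - ca.gamma_s)
    s_e = math.sin(theta - ca.gamma_e)
    return (1 if s_s > 0 else -1), (1 if s_e > 0 else -1)


def classify_sector(ca: CharacteristicAngles, theta: float) -> Sector:
    """Sector containing the force direction ``theta``.

    The label records the torque sign pair, the class is TCD when the
    signs coincide, and the per-joint muscle pattern maps positive
    (counter-clockwise) torque to the flexors.

    Raises
    ------
    OnBoundary
        If ``theta`` lies within 1e-12 of a force singular point, where
        one torque vanishes and the sign pair is undefined.
    """
    theta = _wrap(theta)
    fsp = force_singular_points(ca)
    for p in fsp:
        if min(abs(theta - p), TWO_PI - abs(theta - p)) <= BOUNDARY_TOL:
            raise OnBoundary(f"theta={theta!r} lies on a force singular point")
    sign_s, sign_e = _signs_at(ca, theta)
    # Locate the half-open [start, end) interval between adjacent FSPs.
    start = max((p for p in fsp if p <= theta), default=fsp[-1] - TWO_PI)
    later = [p for p in fsp if p > theta]
    end = later[0] if later else fsp[0] + TWO_PI
    return Sector(
        start=_wrap(start),
        end=_wrap(end),
        label=f"Ms{'+' if sign_s > 0 else '-'}Me{'+' if sign_e > 0 else '-'}",
        klass="TCD" if sign_s == sign_e else "TOD",
        shoulder_muscle=_MUSCLE[sign_s],
        elbow_muscle=_MUSCLE[sign_e],
    )


def synergy_weights(ca: CharacteristicAngles) -> tuple[float, float]:
    """Closed-form sector weights ``(w_TCD, w_TOD)``.

    Equal to the total angular measure of each class over a full force
    turn, divided by 2 pi.
    """
    w_tod = ca.lag / math.pi
    return 1.0 - w_tod, w_tod


def synergy_profile(ca: CharacteristicAngles) -> SynergyProfile:
    """Full sector decomposition for one end-point.

    Sectors are half-open ``[start, end)`` intervals beginning at the
    first sorted FSP.  The degenerate fully-extended-elbow case
    (``gamma_s == gamma_e``) is reported as two TCD sectors with
    ``w_TOD = 0`` rather than four with two of zero width.
    """
    fsp = force_singular_points(ca)
    w_tcd, w_tod = synergy_weights(ca)
    sectors: list[Sector] = []
    for i, start in enumerate(fsp):
        end = fsp[(i + 1) % len(fsp)]
        span = (end - start) % TWO_PI or TWO_PI
        mid = start + 0.5 * span
        sign_s, sign_e = _signs_at(ca, mid)
        sectors.append(
            Sector(
                start=start,
                end=_wrap(end),
                label=f"Ms{'+' if sign_s > 0 else '-'}Me{'+' if sign_e > 0 else '-'}",
                klass="TCD" if sign_s == sign_e else "TOD",
                shoulder_muscle=_MUSCLE[sign_s],
                elbow_muscle=_MUSCLE[sign_e],
            )
        )
    return SynergyProfile(
        fsp=fsp,
        sectors=tuple(sectors),
        w_tcd=w_tcd,
        w_tod=w_tod,
        degenerate=len(fsp) == 2,
    )
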