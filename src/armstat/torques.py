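"""Joint torques of the two-joint arm under a rotating isometric end-point force.

By the principle of virtual work, the shoulder and elbow torques required
to produce an end-point force of amplitude ``F`` in direction ``theta``
are pure sinusoids in theta:

    M_s = F h_s sin(theta - gamma_s)
    M_e = F L_e sin(theta - gamma_e)

with phases set by the characteristic angles and amplitudes by the
shoulder-to-hand distance ``h_s`` and the distal segment length ``L_e``.
Positive torque is counter-clockwise, which for the right-arm layout
corresponds to flexor loading of the joint.

Two independent statics oracles validate the closed form:

* :func:`virtual_work_residual` checks the work identity
  ``M_s dalpha_s + M_e dalpha_e = F . dr`` against the exact end-point
  displacement under a finite joint perturbation (the residual is the
  second-order Taylor remainder, O(delta^2));
* :func:`jacobian_transpose_check` compares against the Jacobian-transpose
  map ``tau = J(alpha)^T F`` of manipulator statics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    ArmGeometry,
    CharacteristicAngles,
    JointConfiguration,
    characteristic_angles,
    forward_kinematics,
)

__all__ = [
    "ForceSpec",
    "TorquePair",
    "TorqueWave",
    "joint_torques",
    "torque_wave",
    "virtual_work_residual",
    "jacobian_transpose_check",
]

#: Sampling density of a full force-direction cycle.
DEFAULT_N_SAMPLES = 1000


@dataclass(frozen=True)
class ForceSpec:
    """Isometric end-point force: amplitude ``F`` (arbitrary units, default
    the unit force) and direction ``theta`` (rad, CCW from the X-axis)."""

    f: float = 1.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("force amplitude must be non-negative")

    @property
    def fx(self) -> float:
        return self.f * math.cos(self.theta)

    @property
    def fy(self) -> float:
        return self.f * math.sin(self.theta)


@dataclass(frozen=True)
class TorquePair:
    """Shoulder and elbow torques (force x length, arbitrary units);
    positive = counter-clockwise = flexor action."""

    m_s: float
    m_e: float


@dataclass(frozen=True)
class TorqueWave:
    """Sampled torque sinusoids over a full force-direction cycle."""

    theta_samples: np.ndarray
    m_s_samples: np.ndarray
    m_e_samples: np.ndarray
    ca: CharacteristicAngles
    f: float

    @property
    def peak_m_s(self) -> float:
        return float(np.max(np.abs(self.m_s_samples)))

    @property
    def peak_m_e(self) -> float:
        return float(np.max(np.abs(self.m_e_samples)))


def joint_torques(
    ca: CharacteristicAngles, force: ForceSpec, geom: ArmGeometry
) -> TorquePair:
    """Shoulder and elbow torques for one force direction."""
    return TorquePair(
        m_s=force.f * ca.h_s * math.sin(force.theta - ca.gamma_s),
        m_e=force.f * geom.l_e * math.sin(force.theta - ca.gamma_e),
    )


def torque_wave(
    ca: CharacteristicAngles,
    f: float = 1.0,
    geom: ArmGeometry | None = None,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> TorqueWave:
    """Sample both torque sinusoids over theta in [0, 2 pi), half-open uniform.

    The shoulder wave leads the elbow wave by the lag ``gamma_e - gamma_s``;
    peak amplitudes approach ``F h_s`` and ``F L_e`` to sampling resolution.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    geom = geom if geom is not None else ArmGeometry()
    theta = np.arange(n_samples) * (2.0 * math.pi / n_samples)
    return TorqueWave(
        theta_samples=theta,
        m_s_samples=f * ca.h_s * np.sin(theta - ca.gamma_s),
        m_e_samples=f * geom.l_e * np.sin(theta - ca.gamma_e),
        ca=ca,
        f=f,
    )


def virtual_work_residual(
    joints: JointConfiguration,
    force: ForceSpec,
    geom: ArmGeometry,
    delta: float = 1e-4,
) -> float:
    """Finite-perturbation check of the virtual-work identity.

    Perturbs both joint angles by ``delta``, displaces the end-point by
    exact forward kinematics (not the small-arc approximation, so the
    residual isolates the first-order identity), and returns

        | M_s delta + M_e delta - (F_x r_x + F_y r_y) |

    which is the second-order Taylor remainder: halving delta shrinks it
    about four-fold.
    """
    if not (0.0 < delta <= 1e-2):
        raise ValueError("delta must lie in (0, 1e-2]")
    ca = characteristic_angles(geom, joints)
    tq = joint_torques(ca, force, geom)
    p0 = forward_kinematics(geom, joints)
    # Perturbed end-point evaluated directly: the kinematic map is entire,
    # so the perturbed angles need not respect the nominal joint ranges.
    a = joints.alpha_s + delta
    b = a + joints.alpha_e + delta
    r_x = geom.l_s * math.cos(a) + geom.l_e * math.cos(b) - p0.x
    r_y = geom.l_s * math.sin(a) + geom.l_e * math.sin(b) - p0.y
    work_joints = tq.m_s * delta + tq.m_e * delta
    work_force = force.fx * r_x + force.fy * r_y
    return abs(work_joints - work_force)


def jacobian_transpose_check(
    joints: JointConfiguration, force: ForceSpec, geom: ArmGeometry
) -> float:
    """Max abs difference between the sinusoid torques and ``J^T F``.

    The kinematic Jacobian ``J = d(x, y)/d(alpha_s, alpha_e)`` maps joint
    rates to end-point velocity; its transpose maps an end-point force to
    the joint torques that balance it.  The difference from the closed-form
    torques is pure roundoff (< 1e-10).
    """
    a, b = joints.alpha_s, joints.alpha_s + joints.alpha_e
    # Columns: d(endpoint)/d(alpha_s), d(endpoint)/d(alpha_e)
    jac = np.array(
        [
            [-geom.l_s * math.sin(a) - geom.l_e * math.sin(b), -geom.l_e * math.sin(b)],
            [geom.l_s * math.cos(a) + geom.l_e * math.cos(b), geom.l_e * math.cos(b)],
        ]
    )
    tau_oracle = jac.T @ np.array([force.fx, force.fy])
    ca = characteristic_angles(geom, joints)
    tq = joint_torques(ca, force, geom)
    return float(max(abs(tq.m_s - tau_oracle[0]), abs(tq.m_e - tau_oracle[1])))
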