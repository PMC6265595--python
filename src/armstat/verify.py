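"""Self-verification suite: statics oracles and route-equivalence checks.

Runs, at a configurable problem size, the package's internal consistency
checks: agreement of the sinusoid torques with the Jacobian-transpose
statics map and with the virtual-work identity on random configurations,
equivalence of the two characteristic-angle computation routes on the
canonical grid, and the global ordering gamma_e >= gamma_s.  Intended for
the ``armstat verify`` command and for quick sanity runs after changes;
the pytest suite exercises the same properties with fixed oracle values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import (
    ArmGeometry,
    JointConfiguration,
    characteristic_angles,
    characteristic_angles_from_endpoint,
    forward_kinematics,
)
from .io import RunConfig, fixture_grid
from .torques import ForceSpec, jacobian_transpose_check, virtual_work_residual

__all__ = ["VerifyReport", "run_verification"]


@dataclass(frozen=True)
class VerifyReport:
    n_random: int
    max_jacobian_difference: float
    max_virtual_work_ratio_error: float
    max_route_difference: float
    min_gamma_ordering_margin: float

    @property
    def passed(self) -> bool:
        return (
            self.max_jacobian_difference < 1e-10
            and self.max_virtual_work_ratio_error < 1.0
            and self.max_route_difference < 1e-9
            and self.min_gamma_ordering_margin >= -1e-12
        )


def run_verification(
    config: RunConfig | None = None, n_random: int = 1000
) -> VerifyReport:
    """Run all internal consistency checks and return their worst margins.

    Random joint configurations and force directions are drawn from the
    config seed; the virtual-work check verifies quadratic convergence of
    the finite-difference residual (the ratio under delta-halving should
    be near 4; its deviation beyond [3.5, 4.5] is reported as an error).
    """
    config = config if config is not None else RunConfig()
    geom = config.geometry
    rng = np.random.default_rng(config.seed)

    max_jac = 0.0
    max_vw_err = 0.0
    for _ in range(n_random):
        joints = JointConfiguration(
            alpha_s=rng.uniform(0.0, math.pi * 0.999),
            alpha_e=rng.uniform(0.05, math.pi * 0.95),
        )
        force = ForceSpec(f=rng.uniform(0.1, 2.0), theta=rng.uniform(0.0, 2 * math.pi))
        max_jac = max(max_jac, jacobian_transpose_check(joints, force, geom))
        r1 = virtual_work_residual(joints, force, geom, delta=1e-3)
        r2 = virtual_work_residual(joints, force, geom, delta=5e-4)
        if r2 > 1e-14:  # ratio meaningless at roundoff level
            ratio = r1 / r2
            max_vw_err = max(max_vw_err, max(0.0, abs(ratio - 4.0) - 0.5))

    max_route = 0.0
    min_margin = math.inf
    for joints in fixture_grid(config):
        ca = characteristic_angles(geom, joints)
        min_margin = min(min_margin, ca.gamma_e - ca.gamma_s)
        ep = forward_kinematics(geom, joints)
        if ep.y >= 0 and geom.equal_lengths:
            ca2 = characteristic_angles_from_endpoint(ep, geom)
            max_route = max(
                max_route,
                abs(ca.gamma_s - ca2.gamma_s),
                abs(ca.gamma_e - ca2.gamma_e),
                abs(ca.h_s - ca2.h_s),
            )
    return VerifyReport(
        n_random=n_random,
        max_jacobian_difference=max_jac,
        max_virtual_work_ratio_error=max_vw_err,
        max_route_difference=max_route,
        min_gamma_ordering_margin=min_margin,
    )
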