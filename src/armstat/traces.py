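"""End-point trace families and the isotropy/anisotropy analysis.

A *trace* is the end-point path obtained by varying one joint angle while
the other is fixed: "shoulder" traces vary alpha_s at fixed alpha_e
(concentric arcs about the shoulder axis), "elbow" traces vary alpha_e at
fixed alpha_s.  Sweeping the fixed angle over the same grid yields a
family of traces covering the working space; the canonical grid steps both
angles by pi/10 through indices 0..9.

Because the characteristic angles are affine in the joint angles
(gamma_e = alpha_s + alpha_e; gamma_s = alpha_s + alpha_e/2 for equal
segments), each family is summarised exactly by least-squares slopes and
adjacent-line spacings:

* shoulder family — slopes d(gamma_s)/d(alpha_s) = d(gamma_e)/d(alpha_s) = 1,
  spacings Delta(gamma_s) = pi/20 and Delta(gamma_e) = pi/10;
* elbow family — slopes 0.5 and 1, spacings both pi/10.

The torque-phase lag gamma_e - gamma_s is constant along every shoulder
trace (the pair of torque sinusoids shifts rigidly: *isotropic* change)
but grows along every elbow trace (*anisotropic*).  Re-plotting the angles
against the end-point's frontal coordinate x gives the X-projection view,
in which the two family kinds produce identical point sets and differ only
in how the points are threaded into lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import GridTooLarge
from .geometry import (
    ArmGeometry,
    JointConfiguration,
    characteristic_angles,
    forward_kinematics,
)

__all__ = [
    "TraceFamily",
    "FamilyReport",
    "build_trace_family",
    "analyze_family",
    "x_projection",
]

Kind = Literal["shoulder", "elbow"]

#: Canonical grid parameters.
DEFAULT_STEP = math.pi / 10
DEFAULT_N = 10

_RECORD_COLUMNS = [
    "kind",
    "fixed_index",
    "varying_index",
    "alpha_s",
    "alpha_e",
    "x",
    "y",
    "h_s",
    "gamma_s",
    "gamma_e",
    "gamma_diff",
]


@dataclass(frozen=True)
class TraceFamily:
    """A family of end-point traces with one joint angle fixed per trace.

    ``records`` holds one row per (fixed, varying) grid pair with the
    end-point coordinates and characteristic angles; for
    ``kind="shoulder"`` the fixed angle is alpha_e and the varying one
    alpha_s, and vice versa for ``kind="elbow"``.
    """

    kind: Kind
    step: float
    n: int
    records: pd.DataFrame  # columns per _RECORD_COLUMNS

    @property
    def fixed_values(self) -> np.ndarray:
        return np.unique(self.records["fixed_index"]) * self.step

    def line(self, fixed_index: int) -> pd.DataFrame:
        """Records of a single trace, ordered by the varying angle."""
        sel = self.records[self.records["fixed_index"] == fixed_index]
        return sel.sort_values("varying_index").reset_index(drop=True)


@dataclass(frozen=True)
class FamilyReport:
    """Slope/spacing constants and isotropy flag of one trace family.

    Slopes are least-squares fits of gamma against the varying angle per
    trace (asserted equal across traces); spacings are mean offsets
    between adjacent fixed-value lines at matched abscissae.  ``isotropy``
    is True when the torque-phase lag gamma_e - gamma_s is constant along
    every trace.  Spacings are NaN when the family has a single line.
    """

    kind: Kind
    slope_gamma_s: float
    slope_gamma_e: float
    spacing_gamma_s: float
    spacing_gamma_e: float
    isotropy: bool
    max_lag_deviation: float


def build_trace_family(
    kind: Kind,
    geom: ArmGeometry | None = None,
    step: float = DEFAULT_STEP,
    n: int = DEFAULT_N,
) -> TraceFamily:
    """Build an n-line family of n-point traces on a uniform angle grid.

    Grid values are computed as ``index * step`` exactly (no running sum).
    Grid points where the end-point degenerates onto the shoulder axis
    cannot occur because the angles stay below pi.

    Raises
    ------
    GridTooLarge
        If ``(n - 1) * step >= pi`` (joint angles must stay below pi).
    """
    if kind not in ("shoulder", "elbow"):
        raise ValueError(f"kind must be 'shoulder' or 'elbow', got {kind!r}")
    if step <= 0:
        raise ValueError("step must be positive")
    if (n - 1) * step >= math.pi:
        raise GridTooLarge(
            f"grid reaches {(n - 1) * step:.4f} rad >= pi; reduce step or n"
        )
    geom = geom if geom is not None else ArmGeometry()
    rows = []
    for k in range(n):  # fixed-angle index
        for i in range(n):  # varying-angle index
            fixed, varying = k * step, i * step
            if kind == "shoulder":
                alpha_s, alpha_e = varying, fixed
            else:
                alpha_s, alpha_e = fixed, varying
            joints = JointConfiguration(alpha_s, alpha_e)
            ep = forward_kinematics(geom, joints)
            ca = characteristic_angles(geom, joints)
            rows.append(
                (kind, k, i, alpha_s, alpha_e, ep.x, ep.y, ca.h_s,
                 ca.gamma_s, ca.gamma_e, ca.lag)
            )
    return TraceFamily(
        kind=kind,
        step=step,
        n=n,
        records=pd.DataFrame(rows, columns=_RECORD_COLUMNS),
    )


def _line_slope(line: pd.DataFrame, column: str, varying: np.ndarray) -> float:
    """Least-squares slope of one gamma column against the varying angle."""
    coeffs = np.polynomial.polynomial.polyfit(varying, line[column].to_numpy(), 1)
    return float(coeffs[1])


def analyze_family(family: TraceFamily) -> FamilyReport:
    """Recover the slope/spacing constants and the isotropy flag.

    Slopes are fitted per line and averaged (the fits agree to roundoff
    because the model is exactly affine); spacings are the mean difference
    between consecutive lines at matched varying-angle indices.
    """
    n = family.n
    slopes_s, slopes_e = [], []
    lag_deviation = 0.0
    lines = [family.line(k) for k in range(n)]
    for line in lines:
        varying = line["varying_index"].to_numpy() * family.step
        if len(line) >= 2:
            slopes_s.append(_line_slope(line, "gamma_s", varying))
            slopes_e.append(_line_slope(line, "gamma_e", varying))
        lag = line["gamma_diff"].to_numpy()
        lag_deviation = max(lag_deviation, float(np.max(np.abs(lag - lag.mean()))))
    if n >= 2:
        spacing_s = float(
            np.mean(
                [
                    lines[k + 1]["gamma_s"].to_numpy() - lines[k]["gamma_s"].to_numpy()
                    for k in range(n - 1)
                ]
            )
        )
        spacing_e = float(
            np.mean(
                [
                    lines[k + 1]["gamma_e"].to_numpy() - lines[k]["gamma_e"].to_numpy()
                    for k in range(n - 1)
                ]
            )
        )
    else:
        spacing_s = spacing_e = math.nan
    return FamilyReport(
        kind=family.kind,
        slope_gamma_s=float(np.mean(slopes_s)) if slopes_s else math.nan,
        slope_gamma_e=float(np.mean(slopes_e)) if slopes_e else math.nan,
        spacing_gamma_s=spacing_s,
        spacing_gamma_e=spacing_e,
        isotropy=lag_deviation < 1e-9,
        max_lag_deviation=lag_deviation,
    )


def x_projection(family: TraceFamily) -> pd.DataFrame:
    """Re-index the family by the end-point's frontal coordinate.

    Returns the records with columns ``kind, fixed_index, varying_index,
    x, gamma_s, gamma_e, gamma_diff``: the same angle data plotted against
    x instead of the varying joint angle.  Over a common grid the
    shoulder- and elbow-family point multisets coincide; only the line
    connectivity (the fixed/varying role of the indices) differs.
    """
    return family.records[
        ["kind", "fixed_index", "varying_index", "x", "gamma_s", "gamma_e", "gamma_diff"]
    ].copy()
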