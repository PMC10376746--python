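"""Static equilibrium of the Planche: segment torques, shoulder position, wrist angle.

The athlete is modelled as eight rigid segments hinged in a straight line
inclined at the body angle β above horizontal, supported only at the wrists.
Taking the wrist as the torque pivot and x as the horizontal coordinate of
the shoulders (positive toward the head), each segment i contributes a
gravitational torque of the form

    T_i = (x + c_i · cos β) · m_i · g          (i = 1..6, head-to-feet chain)
    T_7 = x · m_7 · g · (D_7 + L_8) / (L_7 + L_8)
    T_8 = x · m_8 · g ·  D_8        / (L_7 + L_8)

where c_i is the along-body offset of segment i's centre of gravity from the
shoulders: c_1 = −(L_1 − D_1) for the head (on the head side, hence
negative), c_2 = D_2, c_3 = L_2 + D_3, and c_4..c_6 the cumulative chain
lengths minus the distally referenced D_i.  The arm torques are pure lever
ratios of the shoulder offset; they carry no β dependence.

Balance requires Σ T_i = 0.  Every T_i is affine in x, so the equilibrium
shoulder position has the closed form

    x* = −cos β · N / W,
    N  = Σ_{i=1..6} c_i · m_i,
    W  = Σ_{i=1..6} m_i + m_7 (D_7 + L_8)/(L_7 + L_8) + m_8 D_8/(L_7 + L_8).

The hold is anatomically possible only if |x*| < L_7 + L_8 (the shoulders
cannot sit farther from the wrists than the outstretched arm); at a feasible
x the wrist/arm angle is α = 180° − arccos(x / (L_7 + L_8)).  Smaller α means
a harder balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .anthropometry import SegmentTable

__all__ = [
    "Posture",
    "EquilibriumSolution",
    "DegenerateGeometryError",
    "NoUniqueSolutionError",
    "segment_torques",
    "torque_sum",
    "solve_equilibrium",
    "check_feasibility",
    "arm_angle",
]

#: arccos arguments within this margin outside [-1, 1] are clamped.
_ACOS_CLAMP = 1e-12


class DegenerateGeometryError(ValueError):
    """Geometry makes the model meaningless (e.g. zero arm length)."""


class NoUniqueSolutionError(ValueError):
    """The torque balance has no unique root (all effective weights zero)."""


@dataclass(frozen=True)
class Posture:
    """Body angle β (degrees above horizontal) and shoulder coordinate x (m)."""

    beta_deg: float
    x_m: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.beta_deg < 90.0:
            raise ValueError(f"beta_deg must lie in [0, 90), got {self.beta_deg}")


@dataclass(frozen=True)
class EquilibriumSolution:
    """Balance solution at one body angle β."""

    beta_deg: float
    x_m: float
    feasible: bool
    alpha_deg: float | None
    residual_torque: float

    def __post_init__(self):
        if self.feasible and self.alpha_deg is None:
            raise ValueError("feasible solutions must carry alpha_deg")


def _cog_offsets(table: SegmentTable) -> np.ndarray:
    """Along-body COG offsets c_1..c_6 of the head-to-feet chain (m)."""
    L, D = table.lengths_m, table.cogs_m
    cum = np.cumsum(L[1:6])  # L2, L2+L3, ..., L2+..+L6
    return np.array(
        [
            -(L[0] - D[0]),          # head: COG above the shoulders
            D[1],                    # upper trunk
            L[1] + D[2],             # lower trunk
            cum[2] - D[3],           # thighs  (L2+L3+L4 − D4)
            cum[3] - D[4],           # shanks  (L2+L3+L4+L5 − D5)
            cum[4] - D[5],           # feet    (L2+..+L6 − D6)
        ]
    )


def _arm_levers(table: SegmentTable) -> tuple[float, float]:
    reach = table.arm_reach_m
    if reach <= 0:
        raise DegenerateGeometryError("arm length L7 + L8 must be positive")
    L, D = table.lengths_m, table.cogs_m
    return (D[6] + L[7]) / reach, D[7] / reach


def segment_torques(table: SegmentTable, posture: Posture) -> np.ndarray:
    """Gravitational torque of each segment about the wrist (N·m), T_1..T_8."""
    m, g = table.masses_kg, table.g
    x = posture.x_m
    cos_b = math.cos(math.radians(posture.beta_deg))
    lever7, lever8 = _arm_levers(table)
    chain = (x + _cog_offsets(table) * cos_b) * m[:6] * g
    arms = np.array([x * m[6] * g * lever7, x * m[7] * g * lever8])
    return np.concatenate([chain, arms])


def torque_sum(table: SegmentTable, posture: Posture) -> float:
    """Net torque Σ T_i about the wrist (N·m); zero at equilibrium."""
    return float(segment_torques(table, posture).sum())


def check_feasibility(x_m: float, l7_m: float, l8_m: float) -> bool:
    """Anatomical feasibility: |x| strictly smaller than the arm length."""
    reach = l7_m + l8_m
    if reach <= 0:
        raise DegenerateGeometryError("arm length L7 + L8 must be positive")
    return abs(x_m) < reach


def arm_angle(x_m: float, l7_m: float, l8_m: float) -> float:
    """Wrist/arm angle α = 180° − arccos(x / (L7 + L8)), in degrees.

    Defined on |x| ≤ L7 + L8 (the closed interval: the boundary gives the
    degenerate fully extended postures α = 0° or 180°, even though the
    balance itself is infeasible there).
    """
    reach = l7_m + l8_m
    if reach <= 0:
        raise DegenerateGeometryError("arm length L7 + L8 must be positive")
    ratio = x_m / reach
    if abs(ratio) > 1.0:
        if abs(ratio) - 1.0 <= _ACOS_CLAMP:
            ratio = math.copysign(1.0, ratio)
        else:
            raise ValueError(
                f"|x| = {abs(x_m):.6g} m exceeds the arm length {reach:.6g} m; "
                "gate on check_feasibility first"
            )
    return 180.0 - math.degrees(math.acos(ratio))


def solve_equilibrium(table: SegmentTable, beta_deg: float) -> EquilibriumSolution:
    """Solve Σ T_i(x) = 0 for the shoulder coordinate at body angle β.

    The torque sum is affine in x with slope W·g > 0, so the root is the
    closed form x* = −cos β · N / W.  The returned solution carries the
    feasibility verdict, the wrist angle α when feasible, and the residual
    torque re-evaluated at x* by substitution.
    """
    posture0 = Posture(beta_deg=beta_deg)  # validates β
    m = table.masses_kg
    lever7, lever8 = _arm_levers(table)
    weight = float(m[:6].sum() + m[6] * lever7 + m[7] * lever8)
    if weight <= 0:
        raise NoUniqueSolutionError(
            "all effective segment weights are zero; the torque balance is "
            "satisfied for every x"
        )
    n = float(_cog_offsets(table) @ m[:6])
    x = -math.cos(math.radians(beta_deg)) * n / weight
    residual = torque_sum(table, Posture(beta_deg=posture0.beta_deg, x_m=x))
    l7, l8 = table.length(7), table.length(8)
    feasible = check_feasibility(x, l7, l8)
    alpha = arm_angle(x, l7, l8) if feasible else None
    return EquilibriumSolution(
        beta_deg=beta_deg,
        x_m=x,
        feasible=feasible,
        alpha_deg=alpha,
        residual_torque=residual,
    )
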