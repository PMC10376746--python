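"""Torque balance: segment torques, closed-form equilibrium, wrist angle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from planche import (
    DegenerateGeometryError,
    NoUniqueSolutionError,
    Posture,
    SegmentTable,
    arm_angle,
    check_feasibility,
    segment_torques,
    solve_equilibrium,
    torque_sum,
)

from conftest import random_segment_table


def table_with(masses, lengths=None, cogs=None, **kw):
    lengths = np.full(8, 0.3) if lengths is None else np.asarray(lengths, float)
    cogs = lengths / 2 if cogs is None else np.asarray(cogs, float)
    return SegmentTable(masses_kg=np.asarray(masses, float), lengths_m=lengths, cogs_m=cogs, **kw)


def bisection_x(table: SegmentTable, beta_deg: float) -> float:
    """Independent root of the torque sum in x (the closed form never enters)."""
    f = lambda x: torque_sum(table, Posture(beta_deg=beta_deg, x_m=x))
    span = 10.0 * float(table.lengths_m.sum())
    return brentq(f, -span, span, xtol=1e-13, rtol=8.9e-16)


class TestSegmentTorques:
    def test_zero_masses_zero_torques(self):
        table = table_with(np.zeros(8))
        torques = segment_torques(table, Posture(beta_deg=10.0, x_m=0.2))
        np.testing.assert_array_equal(torques, np.zeros(8))

    def test_lower_trunk_torque_hand_value(self):
        # x = 0, β = 0, only m3 = 10 kg, L2 = 0.30, D3 = 0.25:
        # T3 = (L2 + D3)·m3·g = 0.55 · 10 · 9.81 = 53.955 N·m
        masses = np.zeros(8)
        masses[2] = 10.0
        lengths = np.full(8, 0.3)
        cogs = lengths / 2
        cogs[2] = 0.25
        table = table_with(masses, lengths, cogs)
        torques = segment_torques(table, Posture(beta_deg=0.0, x_m=0.0))
        assert torques[2] == pytest.approx(53.955, abs=1e-12)
        assert np.all(torques[np.arange(8) != 2] == 0)

    def test_upper_arm_torque_lever_ratio(self):
        # x = 0.1, m7 = 4, D7 = 0.15, L7 = 0.30, L8 = 0.25:
        # T7 = 0.1 · 4 · 9.81 · (0.15 + 0.25)/0.55 = 2.85381... N·m
        masses = np.zeros(8)
        masses[6] = 4.0
        lengths = np.full(8, 0.3)
        lengths[7] = 0.25
        table = table_with(masses, lengths)
        torques = segment_torques(table, Posture(beta_deg=0.0, x_m=0.1))
        assert torques[6] == pytest.approx(0.1 * 4 * 9.81 * 0.40 / 0.55, abs=1e-12)

    def test_arm_torques_independent_of_beta(self):
        rng = np.random.default_rng(7)
        table = random_segment_table(rng)
        t0 = segment_torques(table, Posture(beta_deg=0.0, x_m=0.15))
        t20 = segment_torques(table, Posture(beta_deg=20.0, x_m=0.15))
        np.testing.assert_allclose(t0[6:], t20[6:], rtol=0, atol=0)
        assert not np.allclose(t0[:6], t20[:6])


class TestSolveEquilibrium:
    def test_symmetric_body_balances_at_zero(self):
        # head counterweights the upper trunk exactly: N = 0 -> x = 0, α = 90°
        masses = np.zeros(8)
        masses[0] = masses[1] = 2.0
        lengths = np.full(8, 0.2)
        cogs = np.full(8, 0.1)
        sol = solve_equilibrium(table_with(masses, lengths, cogs), beta_deg=0.0)
        assert sol.x_m == pytest.approx(0.0, abs=1e-15)
        assert sol.feasible
        assert sol.alpha_deg == pytest.approx(90.0, abs=1e-12)

    def test_single_segment_balance(self):
        # only the upper trunk has mass: x = -D2; massless arms set the reach
        masses = np.zeros(8)
        masses[1] = 5.0
        lengths = np.full(8, 0.25)
        cogs = lengths / 2
        cogs[1] = 0.2
        sol = solve_equilibrium(table_with(masses, lengths, cogs), beta_deg=0.0)
        assert sol.x_m == pytest.approx(-0.2, abs=1e-15)
        assert sol.feasible  # |x| = 0.2 < L7 + L8 = 0.5
        assert sol.alpha_deg == pytest.approx(180.0 - math.degrees(math.acos(-0.4)), abs=1e-12)

    def test_all_zero_masses_has_no_unique_solution(self):
        with pytest.raises(NoUniqueSolutionError):
            solve_equilibrium(table_with(np.zeros(8)), beta_deg=0.0)

    def test_beta_out_of_range_rejected(self):
        rng = np.random.default_rng(3)
        table = random_segment_table(rng)
        with pytest.raises(ValueError):
            solve_equilibrium(table, beta_deg=90.0)
        with pytest.raises(ValueError):
            solve_equilibrium(table, beta_deg=-1.0)

    @settings(derandomize=True, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1), beta=st.floats(0.0, 20.0))
    def test_closed_form_matches_bisection_oracle(self, seed, beta):
        """Closed-form x agrees with an independent root finder to 1e-9 m."""
        table = random_segment_table(np.random.default_rng(seed))
        sol = solve_equilibrium(table, beta_deg=beta)
        assert sol.x_m == pytest.approx(bisection_x(table, beta), abs=1e-9)
        tol = 1e-9 * table.total_mass_kg * table.g * table.lengths_m.sum()
        assert abs(sol.residual_torque) <= tol

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_alpha_increases_with_beta_when_cog_forward(self, seed):
        """With the body COG in front of the shoulders, x (hence α) rises with β."""
        table = random_segment_table(np.random.default_rng(seed))
        xs = [solve_equilibrium(table, float(b)).x_m for b in range(0, 21)]
        n_sign = -np.sign(xs[0])  # sign of N
        if n_sign > 0:
            assert np.all(np.diff(xs) > 0)
            alphas = [
                solve_equilibrium(table, float(b)).alpha_deg
                for b in range(0, 21)
                if solve_equilibrium(table, float(b)).feasible
            ]
            assert np.all(np.diff(alphas) > 0)

    @settings(derandomize=True, max_examples=30)
    @given(
        seed=st.integers(0, 2**31 - 1),
        length_scale=st.floats(0.2, 5.0),
        mass_scale=st.floats(0.2, 5.0),
    )
    def test_alpha_is_scale_invariant(self, seed, length_scale, mass_scale):
        """Scaling all lengths by one constant and masses by another leaves α fixed."""
        table = random_segment_table(np.random.default_rng(seed))
        scaled = SegmentTable(
            masses_kg=table.masses_kg * mass_scale,
            lengths_m=table.lengths_m * length_scale,
            cogs_m=table.cogs_m * length_scale,
            hand_length_m=table.hand_length_m * length_scale,
            g=table.g,
        )
        a = solve_equilibrium(table, 10.0)
        b = solve_equilibrium(scaled, 10.0)
        assert b.x_m == pytest.approx(a.x_m * length_scale, rel=1e-12)
        assert a.feasible == b.feasible
        if a.feasible:
            assert b.alpha_deg == pytest.approx(a.alpha_deg, abs=1e-9)


class TestFeasibilityAndArmAngle:
    def test_feasibility_boundary_is_strict(self):
        assert check_feasibility(0.0, 0.3, 0.2)
        assert check_feasibility(0.49, 0.3, 0.2)
        assert not check_feasibility(-0.5, 0.3, 0.2)  # |x| == L7 + L8 excluded
        assert not check_feasibility(0.5, 0.3, 0.2)
        assert not check_feasibility(0.7, 0.3, 0.2)

    def test_degenerate_arm_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            check_feasibility(0.1, 0.0, 0.0)
        with pytest.raises(DegenerateGeometryError):
            arm_angle(0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "x, expected",
        [
            (0.0, 90.0),  # arccos(0) = 90
            (-0.25, 60.0),  # x = -(L7+L8)/2 -> 180 - 120
            (0.5, 180.0),  # boundary, fully extended
            (-0.5, 0.0),
        ],
    )
    def test_arm_angle_closed_forms(self, x, expected):
        assert arm_angle(x, 0.3, 0.2) == pytest.approx(expected, abs=1e-12)

    def test_arm_angle_monotone_in_x(self):
        xs = np.linspace(-0.5, 0.5, 101)
        alphas = [arm_angle(x, 0.3, 0.2) for x in xs]
        assert np.all(np.diff(alphas) > 0)

    def test_arm_angle_domain(self):
        with pytest.raises(ValueError):
            arm_angle(0.51, 0.3, 0.2)
        # rounding just past the boundary is clamped
        assert arm_angle(0.5 * (1 + 1e-13), 0.3, 0.2) == pytest.approx(180.0)


def test_posture_validation():
    with pytest.raises(ValueError):
        Posture(beta_deg=-0.1)
    with pytest.raises(ValueError):
        Posture(beta_deg=90.0)
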