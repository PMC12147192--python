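import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comtransfer.lipm_core import (
    PendulumState,
    ProjectionStatus,
    closed_form_magnitude,
    eigenfrequency,
    lipm_trajectory,
    orbital_energy,
    projected_transfer_magnitude,
    stationary_time,
)
from conftest import rk4_passive_min_distance


class TestEigenfrequency:
    def test_unit_height_ratio(self):
        assert eigenfrequency(9.81) == pytest.approx(1.0)

    def test_one_meter(self):
        assert eigenfrequency(1.0) == pytest.approx(3.1321, abs=1e-4)

    @pytest.mark.parametrize("bad", [0.0, -0.5])
    def test_nonpositive_height_rejected(self, bad):
        with pytest.raises(ValueError):
            eigenfrequency(bad)


class TestTrajectory:
    def test_initial_position(self):
        s = PendulumState(x0=-0.08, v0=0.1, height=1.0)
        assert lipm_trajectory(s, 0.0) == s.x0

    def test_hand_evaluated_point(self):
        s = PendulumState(x0=-0.10, v0=0.0, height=1.0)
        assert lipm_trajectory(s, 0.2) == pytest.approx(
            -0.10 * math.cosh(0.62642), abs=1e-6)
        assert lipm_trajectory(s, 0.2) == pytest.approx(-0.1203, abs=1e-4)

    def test_negative_time_rejected(self):
        s = PendulumState(x0=-0.1, v0=0.1, height=1.0)
        with pytest.raises(ValueError):
            lipm_trajectory(s, -0.01)

    def test_matches_rk4_integration(self):
        """The closed form tracks a fine RK4 integration of the same ODE."""
        s = PendulumState(x0=-0.10, v0=0.12, height=0.95)
        om2 = s.omega**2
        x, v, dt = s.x0, s.v0, 1e-5
        for i in range(50000):
            t = i * dt
            if i % 5000 == 0:
                assert lipm_trajectory(s, t) == pytest.approx(x, abs=1e-9)
            k1x, k1v = v, om2 * x
            k2x, k2v = v + 0.5 * dt * k1v, om2 * (x + 0.5 * dt * k1x)
            k3x, k3v = v + 0.5 * dt * k2v, om2 * (x + 0.5 * dt * k2x)
            k4x, k4v = v + dt * k3v, om2 * (x + dt * k3x)
            x += dt / 6 * (k1x + 2 * k2x + 2 * k3x + k4x)
            v += dt / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)


class TestStationaryTime:
    def test_zero_velocity_is_already_at_minimum(self):
        t, status = stationary_time(PendulumState(x0=-0.1, v0=0.0, height=1.0))
        assert status is ProjectionStatus.VALID
        assert t == 0.0

    def test_hand_evaluated(self):
        t, status = stationary_time(PendulumState(x0=-0.10, v0=0.15, height=1.0))
        assert status is ProjectionStatus.VALID
        assert t == pytest.approx(math.atanh(0.15 / (3.1321 * 0.10)) / 3.1321, abs=1e-4)
        assert t == pytest.approx(0.1666, abs=2e-4)

    def test_fall_over_pivot(self):
        t, status = stationary_time(PendulumState(x0=-0.05, v0=0.20, height=1.0))
        assert status is ProjectionStatus.FALL_OVER_PIVOT
        assert t is None

    def test_receding(self):
        t, status = stationary_time(PendulumState(x0=-0.1, v0=-0.05, height=1.0))
        assert status is ProjectionStatus.RECEDING

    def test_degenerate_over_pivot(self):
        with pytest.raises(ValueError):
            stationary_time(PendulumState(x0=0.0, v0=0.1, height=1.0))


class TestProjection:
    def test_zero_velocity_identity(self):
        p = projected_transfer_magnitude(PendulumState(x0=-0.10, v0=0.0, height=1.3))
        assert p.status is ProjectionStatus.VALID
        assert p.magnitude == pytest.approx(-0.10)
        assert p.fp_coefficient == pytest.approx(1.0)
        assert p.v_component == 0.0

    def test_worked_decomposition(self):
        p = projected_transfer_magnitude(PendulumState(x0=-0.10, v0=0.15, height=1.0))
        assert p.magnitude == pytest.approx(-0.0878, abs=1e-4)
        assert p.fp_component == pytest.approx(-0.1139, abs=1e-4)
        assert p.v_component == pytest.approx(0.0261, abs=1e-4)
        assert p.fp_coefficient == pytest.approx(1.139, abs=1e-3)
        assert p.v_coefficient == pytest.approx(0.1742, abs=1e-3)

    def test_fall_over_pivot_has_no_magnitude(self):
        p = projected_transfer_magnitude(PendulumState(x0=-0.05, v0=0.20, height=1.0))
        assert p.status is ProjectionStatus.FALL_OVER_PIVOT
        assert p.magnitude is None

    def test_receding_projects_to_current_position(self):
        p = projected_transfer_magnitude(PendulumState(x0=-0.09, v0=-0.1, height=1.0))
        assert p.status is ProjectionStatus.RECEDING
        assert p.magnitude == -0.09


class TestClosedForm:
    def test_zero_velocity(self):
        assert closed_form_magnitude(
            PendulumState(x0=-0.07, v0=0.0, height=1.0)) == -0.07

    def test_hand_evaluated(self):
        m = closed_form_magnitude(PendulumState(x0=-0.10, v0=0.15, height=1.0))
        assert m == pytest.approx(-0.08779, abs=1e-5)

    def test_boundary_limit_goes_to_zero(self):
        om = eigenfrequency(1.0)
        m = closed_form_magnitude(
            PendulumState(x0=-0.10, v0=0.999999 * om * 0.10, height=1.0))
        assert abs(m) < 2e-4

    def test_fall_over_rejected(self):
        with pytest.raises(ValueError):
            closed_form_magnitude(PendulumState(x0=-0.05, v0=0.20, height=1.0))


class TestProperties:
    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(x0=st.floats(-0.25, -0.02), frac=st.floats(0.0, 0.95),
           height=st.floats(0.8, 1.1))
    def test_closed_form_equivalence_and_closure(self, x0, frac, height):
        """The evaluated projection equals the orbital-energy closed form
        and decomposes exactly into its two components."""
        s = PendulumState(x0=x0, v0=frac * eigenfrequency(height) * abs(x0),
                          height=height)
        p = projected_transfer_magnitude(s)
        assert p.status is ProjectionStatus.VALID
        assert p.magnitude == pytest.approx(closed_form_magnitude(s), abs=1e-12)
        assert p.fp_component + p.v_component == p.magnitude  # float-exact sum
        assert p.fp_coefficient >= 1.0
        assert p.v_coefficient >= 0.0
        assert abs(p.magnitude) <= abs(s.x0) + 1e-15

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(x0=st.floats(-0.25, -0.03), frac=st.floats(0.05, 0.9),
           height=st.floats(0.8, 1.1))
    def test_projection_conserved_along_passive_trajectory(self, x0, frac, height):
        """The projection is a function of the conserved orbital energy, so
        every point of a passive trajectory before the minimum projects to
        the same magnitude."""
        s = PendulumState(x0=x0, v0=frac * eigenfrequency(height) * abs(x0),
                          height=height)
        ref = projected_transfer_magnitude(s).magnitude
        t_star, _ = stationary_time(s)
        om = s.omega
        for t in np.linspace(0.0, 0.95 * t_star, 7):
            x = lipm_trajectory(s, t)
            v = om * s.x0 * math.sinh(om * t) + s.v0 * math.cosh(om * t)
            p = projected_transfer_magnitude(PendulumState(x0=x, v0=v, height=height))
            assert p.magnitude == pytest.approx(ref, abs=1e-9)

    def test_monotonicity_in_velocity_and_placement(self):
        om = eigenfrequency(1.0)
        mags = [closed_form_magnitude(PendulumState(-0.12, v, 1.0))
                for v in np.linspace(0.0, 0.9 * om * 0.12, 20)]
        assert np.all(np.diff(mags) > 0)  # toward zero as v0 grows
        mags = [closed_form_magnitude(PendulumState(x, 0.10, 1.0))
                for x in np.linspace(-0.06, -0.25, 20)]
        assert np.all(np.diff(mags) < 0)  # more negative as |x0| grows

    def test_rk4_oracle_agreement(self):
        """Closed-form minimum distance matches a fine RK4 integration of
        the passive pendulum for a batch of random valid states."""
        rng = np.random.default_rng(42)
        n = 200
        height = rng.uniform(0.8, 1.1, n)
        om = np.sqrt(9.81 / height)
        x0 = rng.uniform(-0.25, -0.02, n)
        v0 = rng.uniform(0.0, 0.95, n) * om * np.abs(x0)
        expected = np.array([
            closed_form_magnitude(PendulumState(x, v, h))
            for x, v, h in zip(x0, v0, height)
        ])
        oracle = rk4_passive_min_distance(x0, v0, om, t_end=0.65, dt=1e-4)
        assert np.max(np.abs(expected - oracle)) < 1e-6


def test_orbital_energy_sign_convention():
    s = PendulumState(x0=-0.1, v0=0.1, height=1.0)
    assert orbital_energy(s) < 0  # bounded motion: minimum distance exists
    s2 = PendulumState(x0=-0.05, v0=0.5, height=1.0)
    assert orbital_energy(s2) > 0  # falls over the pivot
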