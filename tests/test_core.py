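"""Stokes physics: closed forms against independent SI-unit and ODE oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

import spherefall as sf
from spherefall.errors import InvalidParameterError
from spherefall.units import water_viscosity_mpa_s


def si_terminal_velocity_um_s(rho_s, rho_l, eta_mpa_s, r_um, g=9.80665):
    """Independent oracle: Stokes terminal velocity computed entirely in SI."""
    delta_rho = rho_s - rho_l  # fg/µm³ is numerically kg/m³
    r_m = r_um * 1e-6
    eta = eta_mpa_s * 1e-3  # Pa·s
    vt_m_s = (2.0 / 9.0) * (g / eta) * delta_rho * r_m**2
    return vt_m_s * 1e6


class TestTerminalVelocity:
    def test_neutral_buoyancy_gives_zero(self, medium):
        s = sf.SpherePhysical(30.0, medium.density_fg_um3)
        assert sf.terminal_velocity(s, medium) == 0.0

    def test_matches_si_oracle(self, medium):
        s = sf.SpherePhysical(25.0, 1050.0)
        expected = si_terminal_velocity_um_s(1050.0, 1000.0, 1.0, 25.0)
        vt = sf.terminal_velocity(s, medium)
        assert vt == pytest.approx(expected, rel=1e-10)
        assert vt == pytest.approx(68.1, abs=0.05)

    def test_quadratic_radius_scaling(self, medium):
        v1 = sf.terminal_velocity(sf.SpherePhysical(20.0, 1040.0), medium)
        v2 = sf.terminal_velocity(sf.SpherePhysical(40.0, 1040.0), medium)
        assert v2 == pytest.approx(4.0 * v1, rel=1e-12)

    def test_buoyant_sample_warns_and_is_negative(self, medium):
        s = sf.SpherePhysical(30.0, 980.0)
        with pytest.warns(sf.BuoyantSampleWarning):
            vt = sf.terminal_velocity(s, medium)
        assert vt < 0

    def test_invalid_parameters_raise(self, medium):
        with pytest.raises(InvalidParameterError):
            sf.SpherePhysical(-1.0, 1050.0)
        with pytest.raises(InvalidParameterError):
            sf.MediumState(0.0, 1000.0)

    @given(
        rho=st.floats(900.0, 1500.0),
        r=st.floats(1.0, 500.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_density_and_radius(self, rho, r):
        m = sf.MediumState(1.0, 1000.0)
        s0 = sf.SpherePhysical(r, rho)
        denser = sf.SpherePhysical(r, rho + 10.0)
        bigger = sf.SpherePhysical(r * 1.5, 1100.0)
        ref = sf.SpherePhysical(r, 1100.0)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert sf.terminal_velocity(denser, m) > sf.terminal_velocity(s0, m)
                assert sf.terminal_velocity(bigger, m) > sf.terminal_velocity(ref, m)


class TestTransientTime:
    def test_one_micron_cell_is_tens_of_nanoseconds(self, medium):
        """1 µm diameter, 1020 fg/µm³ in 1 mPa·s → 57 ns ≈ 60 ns at 1 s.f."""
        tau = sf.transient_time(sf.SpherePhysical(0.5, 1020.0), medium)
        assert tau == pytest.approx(5.6667e-8, rel=1e-4)
        # one significant figure in nanoseconds
        assert round(tau * 1e9, -1) == 60

    def test_hundred_micron_sample_si_oracle(self, medium):
        tau = sf.transient_time(sf.SpherePhysical(50.0, 1020.0), medium)
        # SI: tau = (2/9) rho r² / eta = (2/9)*1020*(50e-6)²/1e-3
        expected = (2.0 / 9.0) * 1020.0 * (50e-6) ** 2 / 1e-3
        assert tau == pytest.approx(expected, rel=1e-10)
        assert tau == pytest.approx(5.67e-4, rel=1e-3)

    def test_quadratic_scaling(self, medium):
        t1 = sf.transient_time(sf.SpherePhysical(10.0, 1020.0), medium)
        t2 = sf.transient_time(sf.SpherePhysical(40.0, 1020.0), medium)
        assert t2 == pytest.approx(16.0 * t1, rel=1e-12)

    def test_monotone_with_radius_squared(self, medium):
        radii = np.linspace(5, 200, 20)
        taus = [sf.transient_time(sf.SpherePhysical(r, 1020.0), medium) for r in radii]
        assert np.all(np.diff(taus) > 0)


class TestDensityInversion:
    def test_zero_velocity_returns_medium_density(self, medium):
        assert sf.density_from_terminal_velocity(0.0, 40.0, medium) == medium.density_fg_um3

    def test_inverse_of_si_oracle(self, medium):
        rho = sf.density_from_terminal_velocity(68.1, 25.0, medium)
        assert rho == pytest.approx(1050.0, abs=0.01)

    @given(rho=st.floats(950.0, 1400.0), r=st.floats(0.5, 400.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_identity(self, rho, r):
        """density∘velocity is the identity on mass density to 1e-12."""
        import warnings

        m = sf.MediumState(0.93, 1004.0)
        s = sf.SpherePhysical(r, rho)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vt = sf.terminal_velocity(s, m)
        back = sf.density_from_terminal_velocity(vt, r, m)
        assert back == pytest.approx(rho, rel=1e-12)


class TestWeight:
    def test_lightest_spheroid_worked_example(self):
        """95 µm diameter at 1024 fg/µm³ weighs ≈ 460 ng (2 s.f.)."""
        w = sf.weight_ng(1024.0, 95.0 / 2.0)
        assert w == pytest.approx(459.7, abs=0.05)
        assert float(f"{w:.2g}") == 460.0

    def test_zero_radius(self):
        assert sf.weight_ng(1050.0, 0.0) == 0.0

    def test_independent_volume_calculation(self):
        # V(d=100 µm) = 523598.78 µm³ by hand; at 1000 fg/µm³ → 523.6 ng
        w = sf.weight_ng(1000.0, 50.0)
        assert w == pytest.approx(523.5988, abs=1e-3)

    def test_negative_radius_raises(self):
        with pytest.raises(InvalidParameterError):
            sf.weight_ng(1000.0, -1.0)


class TestKinematics:
    def test_velocity_boundary_values(self):
        assert sf.velocity_at_time(0.0, 5.0, 100.0, 0.2) == pytest.approx(5.0)
        assert sf.velocity_at_time(50.0, 5.0, 100.0, 0.2) == pytest.approx(100.0)
        # one time constant
        v = sf.velocity_at_time(0.2, 5.0, 100.0, 0.2)
        assert v == pytest.approx(100.0 + (5.0 - 100.0) / math.e, rel=1e-12)

    def test_velocity_monotone_no_overshoot(self):
        t = np.linspace(0, 2, 500)
        v = sf.velocity_at_time(t, 0.0, 250.0, 0.3)
        assert np.all(np.diff(v) > 0)
        assert np.all(v <= 250.0)

    def test_position_boundary_and_uniform_motion(self):
        assert sf.position_at_time(0.0, 7.0, 1.0, 2.0, 0.5) == pytest.approx(7.0)
        # v0 == vT: pure uniform motion
        y = sf.position_at_time(3.0, 10.0, 120.0, 120.0, 0.5)
        assert y == pytest.approx(10.0 + 120.0 * 3.0, rel=1e-14)

    def test_position_derivative_matches_velocity(self):
        """Central finite difference of position equals v(t) to <1e-6 rel."""
        tau, v0, vt, y0 = 0.3, 10.0, 300.0, 50.0
        h = 1e-4 * tau
        for t in [0.05, 0.3, 0.9]:
            num = (
                sf.position_at_time(t + h, y0, v0, vt, tau)
                - sf.position_at_time(t - h, y0, v0, vt, tau)
            ) / (2 * h)
            assert num == pytest.approx(sf.velocity_at_time(t, v0, vt, tau), rel=1e-6)

    def test_position_approaches_asymptote(self):
        tau, v0, vt, y0 = 0.2, 0.0, 400.0, 10.0
        t = 50 * tau
        asymptote = y0 + vt * t + (v0 - vt) * tau
        y = sf.position_at_time(t, y0, v0, vt, tau)
        assert abs(y - asymptote) < 1e-9 * abs(vt * t)

    def test_invalid_tau_raises(self):
        with pytest.raises(InvalidParameterError):
            sf.velocity_at_time(1.0, 0.0, 10.0, 0.0)
        with pytest.raises(InvalidParameterError):
            sf.position_at_time(1.0, 0.0, 0.0, 10.0, -1.0)


class TestOdeOracle:
    def test_equation_of_motion_integrates_to_closed_form(self, medium, constants):
        """Numerically integrating m a = (ρs-ρl)V g - k v reproduces the
        exponential velocity law and its integral to < 1e-6 relative."""
        s = sf.SpherePhysical(45.0, 1050.0)
        k = sf.friction_coefficient(s.radius_um, medium)
        ms = s.mass_fg
        drive = (s.mass_density_fg_um3 - medium.density_fg_um3) * s.volume_um3 * constants.g_um_s2
        vt = sf.terminal_velocity(s, medium, constants)
        tau = sf.transient_time(s, medium)
        v0, y0 = 0.25 * vt, 5.0
        t_end = 8.0 * tau

        def rhs(t, state):
            y, v = state
            return [v, (drive - k * v) / ms]

        sol = solve_ivp(
            rhs, (0.0, t_end), [y0, v0], rtol=1e-10, atol=1e-14,
            dense_output=True, method="DOP853",
        )
        t_eval = np.linspace(0.1 * tau, t_end, 25)
        y_num, v_num = sol.sol(t_eval)
        v_closed = sf.velocity_at_time(t_eval, v0, vt, tau)
        y_closed = sf.position_at_time(t_eval, y0, v0, vt, tau)
        assert np.allclose(v_num, v_closed, rtol=1e-6)
        assert np.allclose(y_num, y_closed, rtol=1e-6)


class TestUnits:
    def test_si_and_internal_units_agree(self, medium):
        """Eq. computed in µm–fg–s and independently in SI agree to 1e-10."""
        for rho, r in [(1024.0, 47.5), (1046.0, 97.5), (1050.0, 10.0)]:
            internal = sf.terminal_velocity(sf.SpherePhysical(r, rho), medium)
            si = si_terminal_velocity_um_s(rho, 1000.0, 1.0, r)
            assert internal == pytest.approx(si, rel=1e-10)

    def test_water_viscosity_helper(self):
        assert water_viscosity_mpa_s(20.0) == pytest.approx(1.002, abs=1e-3)
        assert water_viscosity_mpa_s(25.0) == pytest.approx(0.890, abs=0.01)
        assert water_viscosity_mpa_s(37.0) == pytest.approx(0.69, abs=0.02)
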