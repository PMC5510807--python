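import numpy as np
import pytest
from scipy.optimize import brentq

import ciliaflow as cf
from ciliaflow import TracerExited, TracerStalled
from ciliaflow.envelope import EnvelopeModelConfig


def make_cfg(**overrides):
    kwargs = dict(cbf=14.0, cba=7.5, wavelength=13.0, h=87.5, rho_c=0.84)
    kwargs.update(overrides)
    return EnvelopeModelConfig.from_beat_params(**kwargs)


class TestEnvelopeKinematics:
    def test_reference_positions(self):
        cfg = make_cfg()
        x, y = cf.envelope_position(0.0, 0.0, cfg)
        assert (x, y) == pytest.approx((-cfg.a, 0.0))
        t_quarter = (np.pi / 2) / cfg.omega
        x, y = cf.envelope_position(0.0, t_quarter, cfg)
        assert x == pytest.approx(0.0, abs=1e-12)
        assert y == pytest.approx(cfg.beta * cfg.a)

    def test_orbit_is_clockwise_ellipse_for_positive_beta(self):
        cfg = make_cfg()
        t = np.linspace(0, 2 * np.pi / cfg.omega, 200, endpoint=False)
        x, y = cf.envelope_position(np.zeros_like(t), t, cfg)
        # on the ellipse of semi-axes (a, |beta| a)
        np.testing.assert_allclose(
            (x / cfg.a) ** 2 + (y / (cfg.beta * cfg.a)) ** 2, 1.0,
            rtol=1e-10)
        # signed area of the orbit: negative = clockwise (y up)
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area < 0

    def test_metachronal_phase_vanishes_at_long_wavelength(self):
        cfg_inf = make_cfg(wavelength=1e9)
        x0, y0 = cf.envelope_position(50.0, 0.01, cfg_inf)
        phase = cfg_inf.omega * 0.01
        assert x0 == pytest.approx(50.0 - cfg_inf.a * np.cos(phase),
                                   abs=1e-6)
        assert y0 == pytest.approx(
            cfg_inf.beta * cfg_inf.a * np.sin(phase), abs=1e-6)

    def test_wall_velocity_is_orbit_derivative(self):
        cfg = make_cfg()
        eps = 1e-7
        for t in (0.0, 0.013, 0.031):
            x1, y1 = cf.envelope_position(5.0, t + eps, cfg)
            x0, y0 = cf.envelope_position(5.0, t - eps, cfg)
            u, v = cf.wall_velocity(5.0, t, cfg)
            assert u == pytest.approx((x1 - x0) / (2 * eps), rel=1e-5)
            assert v == pytest.approx((y1 - y0) / (2 * eps), rel=1e-5)


class TestScalarRelations:
    @pytest.mark.parametrize("rho,expected", [
        (1.0, 0.0),
        (0.5, 375.0),
        (0.84, 750 * 0.16 ** 2 / 0.84),     # ≈ 22.857
    ])
    def test_slip_length_from_density(self, rho, expected):
        assert cf.phi_calc(rho) == pytest.approx(expected, abs=1e-9)

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            cf.phi_calc(0.0)

    def test_stokes_number_magnitude_and_scalings(self):
        st_k = cf.stokes_number(2.25e-6, 1000.0, 2 * np.pi * 10, 1e-3)
        assert st_k == pytest.approx(7.1e-5, rel=0.01)
        assert cf.stokes_number(2.25e-6, 1000.0, 0.0) == 0.0
        assert cf.stokes_number(4.5e-6, 1000.0, 2 * np.pi * 10) \
            == pytest.approx(4 * st_k)
        bead = cf.BeadPhysics(radius_um=2.25, density_kg_m3=1000.0)
        assert bead.stokes_number(2 * np.pi * 10) == pytest.approx(st_k)
        assert bead.mass_kg == pytest.approx(
            4 / 3 * np.pi * (2.25e-6) ** 3 * 1000.0)


class TestSolveFlow:
    def test_no_beating_gives_zero_field(self):
        cfg = make_cfg(cba=0.0)
        field = cf.solve_flow(cfg)
        u, v = field.velocity(np.linspace(0, 13, 7), np.linspace(1, 80, 7),
                              0.01)
        assert np.all(u == 0) and np.all(v == 0)

    def test_boundary_residual_below_tolerance(self):
        field = cf.solve_flow(make_cfg())
        assert field.boundary_residual() < 1e-6

    def test_divergence_free(self):
        field = cf.solve_flow(make_cfg())
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 13, 30)
        y = rng.uniform(0.5, 80, 30)
        eps = 1e-4
        dudx = (field.velocity(x + eps, y, 0.02)[0]
                - field.velocity(x - eps, y, 0.02)[0]) / (2 * eps)
        dvdy = (field.velocity(x, y + eps, 0.02)[1]
                - field.velocity(x, y - eps, 0.02)[1]) / (2 * eps)
        cfg = field.cfg
        assert np.abs(dudx + dvdy).max() / (cfg.a * cfg.omega) < 1e-6

    def test_periodicity_in_x_and_t(self):
        cfg = make_cfg()
        field = cf.solve_flow(cfg)
        u0, v0 = field.velocity(3.0, 5.0, 0.017)
        u1, v1 = field.velocity(3.0 + cfg.wavelength, 5.0, 0.017)
        u2, v2 = field.velocity(3.0, 5.0, 0.017 + 2 * np.pi / cfg.omega)
        assert (u1, v1) == pytest.approx((u0, v0), rel=1e-9)
        assert (u2, v2) == pytest.approx((u0, v0), rel=1e-9)

    def test_stagnant_above_channel_height(self):
        cfg = make_cfg()
        field = cf.solve_flow(cfg)
        u, v = field.velocity(np.linspace(0, 13, 9),
                              np.full(9, cfg.h), 0.01)
        scale = cfg.a * cfg.omega
        assert np.abs(u).max() / scale < 1e-12
        assert np.abs(v).max() / scale < 1e-12

    def test_perfect_slip_transmits_no_momentum(self):
        free = cf.solve_flow(make_cfg(phi=1e7, rho_c=None))
        tight = cf.solve_flow(make_cfg(rho_c=0.95))
        xs = np.linspace(0, 13, 17)
        u_free, _ = free.velocity(xs, np.full_like(xs, 2.0), 0.01)
        u_tight, _ = tight.velocity(xs, np.full_like(xs, 2.0), 0.01)
        assert np.abs(u_free).max() < 1e-3 * np.abs(u_tight).max()

    def test_oscillatory_part_linear_in_amplitude(self):
        """Stokes linearity: the wave-locked field scales with the orbit
        amplitude; the steady streaming scales with its square."""
        f1 = cf.solve_flow(make_cfg(cba=4.0))
        f2 = cf.solve_flow(make_cfg(cba=8.0))
        xs = np.linspace(0, 13, 11)
        ys = np.linspace(0.5, 20, 11)
        osc1 = f1.velocity(xs, ys, 0.01)[0] - f1.mean_profile(ys)
        osc2 = f2.velocity(xs, ys, 0.01)[0] - f2.mean_profile(ys)
        np.testing.assert_allclose(osc2, 2.0 * osc1, rtol=1e-9, atol=1e-12)
        assert f2.mean_uw == pytest.approx(4.0 * f1.mean_uw, rel=1e-9)

    def test_zero_net_vertical_flux(self):
        cfg = make_cfg()
        field = cf.solve_flow(cfg)
        xs = np.linspace(0, cfg.wavelength, 4001)
        for y in (2.0, 10.0, 40.0):
            _, v = field.velocity(xs, np.full_like(xs, y), 0.007)
            flux = np.trapezoid(v, xs)
            assert abs(flux) / (cfg.a * cfg.omega * cfg.wavelength) < 1e-6

    def test_steady_uniform_solver_matches_analytic_stokes(self):
        for phi in (0.0, 20.0):
            y, u = cf.solve_steady_uniform(50.0, 80.0, phi)
            analytic = 50.0 * (80.0 - y) / (80.0 + phi)
            np.testing.assert_allclose(u, analytic, rtol=1e-9, atol=1e-9)


class _SteadyField:
    def __init__(self, fn):
        self.fn = fn

    def velocity(self, x, y, t):
        return self.fn(x, y, t)


class TestAdvection:
    def test_uniform_field_crossing_time(self):
        cfg = make_cfg(lw=50.0)
        field = _SteadyField(lambda x, y, t: (10.0, 0.0))
        traj, tau = cf.advect_tracer(field, 5.0, cfg)
        assert tau == pytest.approx(5.0, rel=1e-8)
        np.testing.assert_allclose(traj[:, 2], 5.0)

    def test_parabolic_field_reproduces_profile_law(self):
        cfg = make_cfg(lw=40.0)
        uw, h = 100.0, 87.5
        field = _SteadyField(
            lambda x, y, t: (uw * (1 - y / h) ** 2, 0.0))
        for y0 in (5.0, 20.0, 50.0):
            _, tau = cf.advect_tracer(field, y0, cfg)
            assert cfg.lw / tau == pytest.approx(uw * (1 - y0 / h) ** 2,
                                                 rel=1e-8)

    def test_oscillation_on_drift_crossing_matches_root_solve(self):
        """x(t) = U t + (A/ω)(1 − cos ωt): the integrator's crossing time
        matches the scalar root of x(t) = L_w."""
        cfg = make_cfg(lw=60.0)
        u_drift, amp, omega = 8.0, 30.0, 2 * np.pi * 10
        field = _SteadyField(
            lambda x, y, t: (u_drift + amp * np.sin(omega * t), 0.0))
        _, tau = cf.advect_tracer(field, 5.0, cfg)
        x_of_t = lambda t: u_drift * t + amp / omega * (1 - np.cos(omega * t))
        # x(t) wiggles, so bracket the *first* crossing by a fine scan
        ts = np.linspace(1e-6, 60.0, 600000)
        first = np.argmax(x_of_t(ts) >= cfg.lw)
        tau_exact = brentq(lambda t: x_of_t(t) - cfg.lw,
                           ts[first - 1], ts[first])
        assert tau == pytest.approx(tau_exact, rel=1e-6)
        # effective velocity approaches the drift for L_w >> A/ω
        assert cfg.lw / tau == pytest.approx(u_drift, rel=0.05)

    def test_exit_through_wall_reported_with_point(self):
        cfg = make_cfg(lw=50.0)
        field = _SteadyField(lambda x, y, t: (1.0, -5.0))
        with pytest.raises(TracerExited) as err:
            cf.advect_tracer(field, 5.0, cfg)
        assert err.value.exit_point[1] == pytest.approx(0.0, abs=1e-6)

    def test_stalled_tracer(self):
        cfg = make_cfg()
        field = _SteadyField(lambda x, y, t: (0.0, 0.0))
        with pytest.raises(TracerStalled):
            cf.advect_tracer(field, 5.0, cfg, time_cap=1.0)

    def test_start_altitude_validated(self):
        field = cf.solve_flow(make_cfg())
        with pytest.raises(ValueError):
            cf.advect_tracer(field, -1.0)


class TestEffectiveVelocityProfile:
    def test_no_beating_reports_zero_velocities(self):
        prof = cf.effective_velocity_profile(make_cfg(cba=0.0),
                                             [5.0, 20.0])
        np.testing.assert_array_equal(prof.v, 0.0)

    def test_profile_monotone_and_intercept_near_h(self, patient1_config):
        grid = np.array([5.0, 10.0, 20.0, 35.0, 55.0, 70.0])
        prof = cf.effective_velocity_profile(patient1_config, grid)
        assert np.all(np.diff(prof.v) < 0)
        res = prof.fit()
        assert res.h == pytest.approx(patient1_config.h, rel=0.10)

    def test_grid_validation(self, patient1_config):
        with pytest.raises(ValueError):
            cf.effective_velocity_profile(patient1_config, [0.0, 5.0])


def test_config_validation_and_json(tmp_path):
    with pytest.raises(ValueError):
        EnvelopeModelConfig(a=1.0, omega=1.0, wavelength=-1, phi=0, h=10)
    with pytest.raises(ValueError):
        EnvelopeModelConfig(a=1.0, omega=1.0, wavelength=10, phi=0, h=10,
                            beta=2.0)
    path = tmp_path / "cfg.json"
    path.write_text('{"cbf_hz": 14, "cba_um": 7.5, "lambda_um": 13, '
                    '"rho_c": 0.84, "h_um": 87.5}')
    cfg = EnvelopeModelConfig.from_json(path)
    assert cfg.a == 3.75
    assert cfg.phi == pytest.approx(cf.phi_calc(0.84))
    assert cfg.beta == 0.14
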