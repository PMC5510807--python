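"""Envelope model of cilia-driven Stokes flow and tracer advection.

The discrete cilia layer is replaced by an undulating material surface
covering the cilia tips (the *envelope*): the tip of the cilium anchored at
abscissa ξ follows an elliptic orbit

    X(ξ, t) = ξ − a·cos(ωt − σkξ),   Y(ξ, t) = βa·sin(ωt − σkξ),

with 2a the major axis (so CBA = 2a), β the signed ellipse ratio (β > 0:
clockwise orbit), ω = 2π·CBF, k = 2π/λ the metachronal wavenumber and
σ = ±1 the travel direction of the metachronal wave.  The envelope velocity
drives an incompressible Stokes flow inside a channel 0 ≤ y ≤ h — the fluid
is stagnant above h — through a Navier-type slip condition on the mean line
of the wall:

    u − ϕ ∂u/∂y = u_wall   at y = 0,

where the slip length ϕ accounts for the partial momentum transfer of a
non-continuous cilia cover and is tied to the cilia density by
ϕ = Λ(1 − ρc)²/ρc with Λ = 750 μm.

Because inertia is negligible (Stokes number ≈ 10⁻⁴ for 4.5 μm polystyrene
beads in water at beat frequencies), the flow is quasi-static and linear:
the oscillatory part is solved exactly, per metachronal mode, by a
biharmonic stream function in y with an exponentially scaled basis (stable
for kh ≫ 1).  That wave-locked part decays over ~λ/2π from the wall and
carries no Eulerian mean.  The steady transport observed over many beat
cycles enters at second order in the orbit amplitude, through the
time-averaged Taylor expansion of the envelope boundary condition off the
mean line (the classical swimming-sheet steady streaming): it acts as an
effective steady slip velocity U_s at the wall.  The steady mean flow it
drives must carry zero velocity *and* zero shear at the stagnant interface
y = h (no momentum flows into the stagnant fluid); with the uniform
pressure gradient of the closed observation cell this fixes the mean
profile to an exact parabola

    ū(y) = U_w·(1 − y/h)²,   U_w = U_s · h/(h + 2ϕ),

whose wall shear is 2μU_w/h — the factor 2 of the efficiency index.
Micro-beads
are massless tracers: integrating dX/dt = u(X, t) across an observation
window of length L_w yields the crossing time τ(y0) and the effective
velocity V_eff(y0) = L_w/τ(y0) — the observable the tracking experiment
measures.

Internal unit system: μm, s, Pa·s; velocities in μm/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import SolverError, TracerExited, TracerStalled

WATER_VISCOSITY = 1.0e-3        # Pa·s
SLIP_CONSTANT_UM = 750.0        # Λ of the density–slip relation
DEFAULT_BETA = 0.14             # ellipse ratio used for all simulations
DEFAULT_WINDOW_UM = 81.92       # 256 px × 0.32 μm field of view


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class EnvelopeModelConfig:
    """All simulator parameters in one validated record.

    ``a`` is the orbit half major axis (μm, CBA = 2a); ``omega`` the beat
    pulsation (rad/s); ``wavelength`` the metachronal wavelength λ (μm);
    ``phi`` the slip length ϕ (μm); ``h`` the channel height above which
    the fluid is stagnant (μm); ``lw`` the observation window length (μm);
    ``mu`` the dynamic viscosity (Pa·s, water by default);
    ``slip_constant`` the Λ of ϕ = Λ(1 − ρc)²/ρc; ``wave_direction`` the
    sign σ of the metachronal travel.
    """

    a: float
    omega: float
    wavelength: float
    phi: float
    h: float
    beta: float = DEFAULT_BETA
    lw: float = DEFAULT_WINDOW_UM
    mu: float = WATER_VISCOSITY
    slip_constant: float = SLIP_CONSTANT_UM
    wave_direction: int = +1

    def __post_init__(self):
        if min(self.wavelength, self.h, self.lw, self.mu,
               self.slip_constant) <= 0:
            raise ValueError("wavelength, h, lw, mu, slip_constant must be "
                             "positive")
        if self.a < 0 or self.phi < 0:
            raise ValueError("a and phi must be non-negative")
        if abs(self.beta) > 1:
            raise ValueError("|beta| must not exceed 1")
        if self.wave_direction not in (-1, +1):
            raise ValueError("wave_direction must be ±1")

    @property
    def k(self) -> float:
        """Metachronal wavenumber 2π/λ (rad/μm)."""
        return 2.0 * np.pi / self.wavelength

    @property
    def cbf(self) -> float:
        return self.omega / (2.0 * np.pi)

    @property
    def cba(self) -> float:
        return 2.0 * self.a

    @classmethod
    def from_beat_params(cls, cbf: float, cba: float, wavelength: float,
                         h: float, rho_c: float | None = None,
                         phi: float | None = None, **kwargs
                         ) -> "EnvelopeModelConfig":
        """Build a config from clinically measured beat parameters.

        The slip length is either given directly (``phi``) or computed
        from the cilia density via :func:`phi_calc`.
        """
        if phi is None:
            if rho_c is None:
                raise ValueError("give either phi or rho_c")
            phi = phi_calc(rho_c, kwargs.get("slip_constant",
                                             SLIP_CONSTANT_UM))
        return cls(a=cba / 2.0, omega=2.0 * np.pi * cbf,
                   wavelength=wavelength, phi=phi, h=h, **kwargs)

    @classmethod
    def from_json(cls, path) -> "EnvelopeModelConfig":
        with open(path) as fh:
            obj = json.load(fh)
        return cls.from_beat_params(
            cbf=obj["cbf_hz"], cba=obj["cba_um"],
            wavelength=obj["lambda_um"], h=obj["h_um"],
            rho_c=obj.get("rho_c"), phi=obj.get("phi_um"),
            beta=obj.get("beta", DEFAULT_BETA),
            lw=obj.get("lw_um", DEFAULT_WINDOW_UM),
            mu=obj.get("mu_pa_s", WATER_VISCOSITY),
            slip_constant=obj.get("lambda_const_um", SLIP_CONSTANT_UM))


@dataclass
class BeadPhysics:
    """Inertial properties of a spherical tracer bead."""

    radius_um: float = 2.25
    density_kg_m3: float = 1050.0       # polystyrene

    @property
    def mass_kg(self) -> float:
        r = self.radius_um * 1e-6
        return (4.0 / 3.0) * np.pi * r ** 3 * self.density_kg_m3

    def stokes_number(self, omega: float,
                      mu: float = WATER_VISCOSITY) -> float:
        return stokes_number(self.radius_um * 1e-6, self.density_kg_m3,
                             omega, mu)


# ---------------------------------------------------------------------------
# Scalar relations
# ---------------------------------------------------------------------------

def envelope_position(xi, t, cfg: EnvelopeModelConfig):
    """Tip position of the cilium anchored at abscissa ``xi`` at time t.

    Reduces to the single-cilium elliptic orbit as λ → ∞ (the metachronal
    phase term 2πξ/λ vanishes).
    """
    xi = np.asarray(xi, dtype=float)
    phase = cfg.omega * t - cfg.wave_direction * cfg.k * xi
    x = xi - cfg.a * np.cos(phase)
    y = cfg.beta * cfg.a * np.sin(phase)
    return x, y


def wall_velocity(xi, t, cfg: EnvelopeModelConfig):
    """Material velocity of the envelope (time derivative of the orbit)."""
    xi = np.asarray(xi, dtype=float)
    phase = cfg.omega * t - cfg.wave_direction * cfg.k * xi
    u = cfg.a * cfg.omega * np.sin(phase)
    v = cfg.beta * cfg.a * cfg.omega * np.cos(phase)
    return u, v


def phi_calc(rho_c: float, slip_constant: float = SLIP_CONSTANT_UM) -> float:
    """Slip length from cilia density: ϕ = Λ(1 − ρc)²/ρc.

    A full cover (ρc = 1) gives the no-slip limit ϕ = 0; ρc → 0 would mean
    infinite slip and is rejected.
    """
    if not 0.0 < rho_c <= 1.0:
        raise ValueError("rho_c must lie in (0, 1]: zero density implies "
                         "an infinite (undefined) slip length")
    return slip_constant * (1.0 - rho_c) ** 2 / rho_c


def stokes_number(radius_m: float, density_kg_m3: float, omega: float,
                  mu: float = WATER_VISCOSITY) -> float:
    """St_k = (2/9) R² ρ_b ω / μ for a sphere in an oscillatory flow.

    St_k ≪ 1 means the bead responds instantly to the fluid — a massless
    tracer.
    """
    if min(radius_m, density_kg_m3, mu) < 0 or omega < 0:
        raise ValueError("all arguments must be non-negative")
    return (2.0 / 9.0) * radius_m ** 2 * density_kg_m3 * omega / mu


# ---------------------------------------------------------------------------
# Stokes solve on the periodic strip
# ---------------------------------------------------------------------------

def _mode_coefficients(k: float, h: float, phi: float,
                       u_hat: complex, v_hat: complex) -> np.ndarray:
    """Exact biharmonic mode solution on the strip with slip at y = 0.

    The stream function of the mode is ψ = Re[f(y)·e^{iφ}] with
    (d²/dy² − k²)² f = 0, written in the overflow-free basis

        f(y) = (A + B·y/h)·e^{−ky} + (C + D·y/h)·e^{−k(h−y)}.

    Boundary conditions: f'(0) − ϕf''(0) = u_hat,
    f(0) − ϕf'(0) = v_hat (wall data), f(h) = f'(h) = 0 (stagnant lid).
    """
    eps = np.exp(-k * h)
    # rows: slip-u at 0, slip-v at 0, f(h)=0, f'(h)=0; cols: A, B, C, D
    m = np.array([
        [-k - phi * k ** 2,
         1.0 / h + 2.0 * phi * k / h,
         (k - phi * k ** 2) * eps,
         (1.0 / h - 2.0 * phi * k / h) * eps],
        [1.0 + phi * k,
         -phi / h,
         (1.0 - phi * k) * eps,
         -phi / h * eps],
        [eps, eps, 1.0, 1.0],
        [-k * eps, (1.0 / h - k) * eps, k, 1.0 / h + k],
    ], dtype=complex)
    rhs = np.array([u_hat, v_hat, 0.0, 0.0], dtype=complex)
    try:
        return np.linalg.solve(m, rhs)
    except np.linalg.LinAlgError as exc:   # pragma: no cover
        raise SolverError(f"mode solve failed: {exc}") from exc


def _mode_f(coeff: np.ndarray, k: float, h: float, y: np.ndarray):
    """f, f', f'' of the scaled-basis mode at altitudes y."""
    a, b, c, d = coeff
    y = np.asarray(y, dtype=float)
    e1 = np.exp(-k * y)
    e2 = np.exp(-k * (h - y))
    p1 = a + b * y / h
    p2 = c + d * y / h
    f = p1 * e1 + p2 * e2
    fp = (b / h - k * p1) * e1 + (d / h + k * p2) * e2
    fpp = (k * k * p1 - 2.0 * k * b / h) * e1 \
        + (k * k * p2 + 2.0 * k * d / h) * e2
    return f, fp, fpp


class FlowField:
    """Incompressible Stokes flow on the x-periodic strip 0 ≤ y ≤ h.

    The field is the superposition of the metachronal travelling mode
    (exact stream-function solution) and the steady streaming parabola
    driven by the effective slip velocity ``u_slip`` (see module
    docstring).  It is λ-periodic in x, 2π/ω-periodic in t and
    divergence-free by construction.
    """

    def __init__(self, cfg: EnvelopeModelConfig, coeff: np.ndarray,
                 u_slip: float = 0.0):
        self.cfg = cfg
        self.coeff = coeff
        self.u_slip = u_slip                        # steady slip U_s, μm/s
        # parabola amplitude: slip condition at y=0 with shear -2 U_w/h
        self.mean_uw = u_slip * cfg.h / (cfg.h + 2.0 * cfg.phi)

    def mean_profile(self, y):
        """Time-averaged (Eulerian) horizontal velocity ū(y), μm/s."""
        return self.mean_uw * (1.0 - np.asarray(y, dtype=float)
                               / self.cfg.h) ** 2

    def _mean_profile_dy(self, y):
        return -2.0 * self.mean_uw / self.cfg.h * (
            1.0 - np.asarray(y, dtype=float) / self.cfg.h)

    def _phase(self, x, t):
        return np.exp(1j * (self.cfg.omega * t
                            - self.cfg.wave_direction * self.cfg.k * x))

    def velocity(self, x, y, t):
        """Fluid velocity (u, v) in μm/s at μm position(s) and time t."""
        cfg = self.cfg
        f, fp, _ = _mode_f(self.coeff, cfg.k, cfg.h, y)
        ph = self._phase(np.asarray(x, dtype=float), t)
        u = np.real(fp * ph) + self.mean_profile(y)
        v = np.real(1j * cfg.wave_direction * cfg.k * f * ph)
        return u, v

    def velocity_dy(self, x, y, t):
        """Analytic ∂(u, v)/∂y — used for boundary-condition residuals."""
        cfg = self.cfg
        _, fp, fpp = _mode_f(self.coeff, cfg.k, cfg.h, y)
        ph = self._phase(np.asarray(x, dtype=float), t)
        du = np.real(fpp * ph) + self._mean_profile_dy(y)
        dv = np.real(1j * cfg.wave_direction * cfg.k * fp * ph)
        return du, dv

    def boundary_residual(self, n_x: int = 32, n_t: int = 8) -> float:
        """Max relative residual of the slip and lid conditions.

        The wall data is the linearized envelope velocity plus the
        steady streaming slip ``u_slip`` (the time-averaged second-order
        term of the envelope expansion).
        """
        cfg = self.cfg
        xs = np.linspace(0.0, cfg.wavelength, n_x, endpoint=False)
        ts = np.linspace(0.0, 2.0 * np.pi / cfg.omega, n_t, endpoint=False) \
            if cfg.omega > 0 else np.array([0.0])
        scale = max(cfg.a * abs(cfg.omega), 1e-300)
        worst = 0.0
        for t in ts:
            u0, v0 = self.velocity(xs, np.zeros_like(xs), t)
            du0, dv0 = self.velocity_dy(xs, np.zeros_like(xs), t)
            uw, vw = wall_velocity(xs, t, cfg)
            res_u = np.abs(u0 - cfg.phi * du0 - uw - self.u_slip)
            res_v = np.abs(v0 - cfg.phi * dv0 - vw)
            uh, vh = self.velocity(xs, np.full_like(xs, cfg.h), t)
            worst = max(worst, res_u.max(), res_v.max(),
                        np.abs(uh).max(), np.abs(vh).max())
        return worst / scale if cfg.a > 0 else worst


def solve_flow(cfg: EnvelopeModelConfig, check_tol: float = 1e-6
               ) -> FlowField:
    """Solve the quasi-static Stokes problem driven by the envelope.

    The wall data (the envelope velocity linearized onto the mean line
    y = 0) is a single travelling harmonic, so the solution is the exact
    per-mode biharmonic field.  The assembled field is verified against
    the boundary conditions to ``check_tol`` (relative to the wall speed
    scale aω); a failure raises :class:`SolverError`.
    """
    if cfg.a == 0.0:
        return FlowField(cfg, np.zeros(4, dtype=complex))
    # wall data in the travelling phase variable φ = ωt − σkx:
    # u_w = aω sinφ = Re[−i aω e^{iφ}],  v_w = βaω cosφ = Re[βaω e^{iφ}]
    u_hat = -1j * cfg.a * cfg.omega
    # v = Re[iσk f e^{iφ}] at the wall must equal Re[βaω e^{iφ}]
    # → f(0) − ϕf'(0) = βaω / (iσk) = −iσ βaω/k
    v_hat = -1j * cfg.wave_direction * cfg.beta * cfg.a * cfg.omega / cfg.k
    coeff = _mode_coefficients(cfg.k, cfg.h, cfg.phi, u_hat, v_hat)
    # steady streaming slip: time average of the second-order term of the
    # envelope boundary expansion, U_s = -<ΔX ∂x u¹ + Y_w ∂y u¹> at y = 0,
    # with ΔX = -a cosφ and Y_w = βa sinφ
    _, fp0, fpp0 = _mode_f(coeff, cfg.k, cfg.h, np.array([0.0]))
    u_slip = (0.5 * cfg.a * cfg.wave_direction * cfg.k * np.imag(fp0[0])
              + 0.5 * cfg.beta * cfg.a * np.imag(fpp0[0]))
    field = FlowField(cfg, coeff, u_slip=float(u_slip))
    res = field.boundary_residual()
    if res > check_tol:
        raise SolverError(
            f"flow solve failed boundary check: relative residual {res:.2e}")
    return field


def solve_steady_uniform(u_wall: float, h: float, phi: float,
                         n: int = 201):
    """Numerical steady Stokes flow for a uniform wall velocity.

    Finite-difference two-point solve of μu'' = 0 on [0, h] with the slip
    condition u(0) − ϕu'(0) = u_wall and u(h) = 0.  (The closed form is
    u(y) = u_wall (h − y)/(h + ϕ); this numerical route exists so the
    solver can be validated against it rather than restated from it.)
    Returns ``(y, u)`` arrays.
    """
    y = np.linspace(0.0, h, n)
    dy = y[1] - y[0]
    m = np.zeros((n, n))
    rhs = np.zeros(n)
    for i in range(1, n - 1):
        m[i, i - 1], m[i, i], m[i, i + 1] = 1.0, -2.0, 1.0
    # one-sided O(dy²) derivative in the slip condition
    m[0, 0] = 1.0 - phi * (-1.5 / dy)
    m[0, 1] = -phi * (2.0 / dy)
    m[0, 2] = -phi * (-0.5 / dy)
    rhs[0] = u_wall
    m[-1, -1] = 1.0
    u = np.linalg.solve(m, rhs)
    return y, u


# ---------------------------------------------------------------------------
# Tracer advection and effective velocity
# ---------------------------------------------------------------------------

def advect_tracer(field, y0: float, cfg: EnvelopeModelConfig | None = None,
                  rtol: float = 1e-8, atol: float = 1e-10,
                  time_cap: float = 2000.0):
    """Integrate a massless tracer from (0, y0) across the window.

    ``field`` is any object with a ``velocity(x, y, t)`` method.  The
    integration (adaptive explicit Runge–Kutta) stops when |x| reaches the
    window length L_w — the crossing may be in either direction, depending
    on the metachronal convention — and returns
    ``(trajectory, tau)`` where ``trajectory`` is an (n, 3) array of
    (t, x, y) and ``tau`` the crossing time.

    Raises :class:`TracerExited` if the tracer leaves through y = 0 or
    y = h, and :class:`TracerStalled` if no crossing occurs within
    ``time_cap`` seconds.
    """
    cfg = cfg or field.cfg
    if not 0.0 < y0 < cfg.h:
        raise ValueError("tracer must start strictly inside the channel")

    def rhs(t, state):
        u, v = field.velocity(state[0], state[1], t)
        return [float(u), float(v)]

    def crossed(t, state):
        return abs(state[0]) - cfg.lw
    crossed.terminal = True

    def exit_bottom(t, state):
        return state[1]
    exit_bottom.terminal = True

    def exit_top(t, state):
        return state[1] - cfg.h
    exit_top.terminal = True

    sol = solve_ivp(rhs, (0.0, time_cap), [0.0, y0],
                    events=[crossed, exit_bottom, exit_top],
                    rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:   # pragma: no cover
        raise SolverError(f"tracer integration failed: {sol.message}")
    traj = np.column_stack([sol.t, sol.y[0], sol.y[1]])
    if len(sol.t_events[1]) or len(sol.t_events[2]):
        which = 1 if len(sol.t_events[1]) else 2
        te = sol.t_events[which][0]
        xe, ye = sol.y_events[which][0]
        raise TracerExited(
            f"tracer exited the channel at ({xe:.2f}, {ye:.2f}) μm, "
            f"t = {te:.3f} s", exit_point=(float(xe), float(ye)))
    if not len(sol.t_events[0]):
        raise TracerStalled(
            f"stalled tracer: no crossing of ±{cfg.lw} μm within "
            f"{time_cap} s")
    tau = float(sol.t_events[0][0])
    return traj, tau


def effective_velocity_profile(cfg: EnvelopeModelConfig, y_grid,
                               rtol: float = 1e-8,
                               time_cap: float = 2000.0):
    """V_eff(y0) = L_w / τ(y0) for each entry altitude.

    Returns a :class:`~ciliaflow.profile.VelocityProfile`.  With no beating
    (a = 0) the crossing time is infinite and the velocities are reported
    as zero.
    """
    from .profile import VelocityProfile

    y_grid = np.asarray(y_grid, dtype=float)
    if np.any((y_grid <= 0) | (y_grid >= cfg.h)):
        raise ValueError("y_grid must lie strictly inside (0, h)")
    if cfg.a == 0.0:
        return VelocityProfile(y=y_grid, v=np.zeros_like(y_grid))
    field = solve_flow(cfg)
    v = np.empty_like(y_grid)
    for i, y0 in enumerate(y_grid):
        _, tau = advect_tracer(field, float(y0), cfg, rtol=rtol,
                               time_cap=time_cap)
        v[i] = cfg.lw / tau
    return VelocityProfile(y=y_grid, v=v)
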