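"""Two-layer viscoelastic ASL flow driven by immersed-boundary cilia.

Solves the incompressible momentum equation

    du/dt + u.grad u = -(1/rho) grad p + nu_s lap u + (1/rho) div tau + f

on the staggered grid of the reduced periodic strip, with the 5-mode
Giesekus extra stress ``tau`` confined to the mucus layer and the cilia
represented by a direct-forcing immersed boundary: the body force ``f`` is
chosen each step so that the fluid velocity interpolated at the cilium
surface markers matches the beat velocity ``U_l``.

Boundary conditions: free slip at the air-mucus interface
(``du_x/dz = du_y/dz = 0``, ``u_z = 0``, ``dp/dz = 0``, ``tau = 0``),
no slip at the epithelium (``u = 0``, ``dp/dz = 0``; an oscillating wall
velocity can be prescribed for benchmark problems), periodic in x' and y',
and ``tau = 0`` throughout the Newtonian PCL below the flat PCL-mucus
interface.

Time scheme (one step):

1. explicit Giesekus stress update from the current velocity gradient;
2. momentum predictor with explicit advection and stress divergence and
   *implicit* (backward-Euler) solvent diffusion, solved as a Helmholtz
   problem per component by FFT in the periodic directions and a tridiagonal
   solve in z -- the solvent diffusion number ``nu dt / dx^2`` is O(10^3) at
   physiological resolution, far beyond any explicit limit;
3. direct forcing: interpolate the predictor at the markers, spread the
   velocity deficit back as a force (optionally iterated, multidirect);
4. pressure-projection: FFT/tridiagonal Poisson solve with Neumann walls,
   making the discrete divergence vanish to round-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cilia import MarkerField
from .grid import GridSpec, divergence
from .ibm import interpolate_velocity, spread_force
from .rheology import GiesekusParams, giesekus_update

__all__ = ["FluidProps", "FlowState", "FlowSolver", "CycleReplay",
           "layer_average_velocity", "apply_flow_bcs"]


@dataclass(frozen=True)
class FluidProps:
    """Newtonian (solvent) properties shared by PCL and mucus."""

    density: float = 1000.0       # kg/m^3
    viscosity: float = 0.001      # Pa s (PCL and Newtonian part of mucus)

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")

    @property
    def nu(self) -> float:
        """Kinematic solvent viscosity (m^2/s)."""
        return self.viscosity / self.density


@dataclass
class FlowState:
    """Staggered velocity, pressure, modal stresses and IBM force."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    tau: np.ndarray | None      # (n_modes, 6) + grid, or None (Newtonian)
    t: float = 0.0


# ---------------------------------------------------------------------------
# small numerical utilities
# ---------------------------------------------------------------------------

def _thomas(diag, lower, upper, rhs):
    """Vectorized tridiagonal solve along the last axis.

    ``diag``/``rhs`` have shape ``(..., n)``; ``lower``/``upper`` are the
    constant off-diagonals (scalars) except that they do not couple across
    the modified boundary rows encoded in ``diag``.
    """
    n = rhs.shape[-1]
    cp = np.empty_like(rhs)
    dp = np.empty_like(rhs)
    cp[..., 0] = upper / diag[..., 0]
    dp[..., 0] = rhs[..., 0] / diag[..., 0]
    for k in range(1, n):
        denom = diag[..., k] - lower * cp[..., k - 1]
        cp[..., k] = upper / denom
        dp[..., k] = (rhs[..., k] - lower * dp[..., k - 1]) / denom
    x = np.empty_like(rhs)
    x[..., -1] = dp[..., -1]
    for k in range(n - 2, -1, -1):
        x[..., k] = dp[..., k] - cp[..., k] * x[..., k + 1]
    return x


def _lateral_eigenvalues(grid: GridSpec):
    """Eigenvalues of the periodic second-difference operator in x' and y'."""
    d2 = grid.dx**2
    kx = np.arange(grid.nx)
    ky = np.arange(grid.ny // 2 + 1)  # rfft along y
    lx = -(2.0 - 2.0 * np.cos(2.0 * np.pi * kx / grid.nx)) / d2
    ly = -(2.0 - 2.0 * np.cos(2.0 * np.pi * ky / grid.ny)) / d2
    return lx[:, None] + ly[None, :]


def apply_flow_bcs(state: FlowState, grid: GridSpec) -> FlowState:
    """Enforce the stored-array parts of the boundary conditions.

    The wall-normal velocity vanishes on both z boundaries (free-slip top,
    no-slip bottom); the tangential/pressure conditions live in the ghost
    handling of the difference operators.  Elastic stress is hard-zeroed in
    the PCL (Newtonian layer) -- its top-boundary zero is applied as a ghost
    value inside the stress-divergence and advection stencils.
    """
    state.w[:, :, 0] = 0.0
    state.w[:, :, -1] = 0.0
    if state.tau is not None:
        state.tau *= grid.mucus_mask()
    return state


def _pad_z_centered(f, bottom: str, top: str, wall_value: float = 0.0):
    """Ghost-pad a cell-centred field in z.

    ``bottom``/``top`` in {'noslip', 'freeslip', 'zero'}: antisymmetric about
    the wall value, symmetric (zero gradient), or zero ghost.
    """
    def ghost(layer, kind):
        if kind == "noslip":
            return 2.0 * wall_value - layer
        if kind == "freeslip":
            return layer.copy()
        return np.zeros_like(layer)

    return np.concatenate([ghost(f[:, :, :1], bottom), f,
                           ghost(f[:, :, -1:], top)], axis=2)


def layer_average_velocity(u: np.ndarray, grid: GridSpec,
                           layer: str = "ASL") -> float:
    """Volume-average of the x'-velocity over a layer (m/s).

    ``layer`` is one of 'PCL' (z below the PCL-mucus interface), 'mucus'
    (above it) or 'ASL' (everything).
    """
    zc = grid.zc()
    if layer == "PCL":
        mask = zc < grid.z_interface
    elif layer == "mucus":
        mask = zc >= grid.z_interface
    elif layer == "ASL":
        mask = np.ones_like(zc, dtype=bool)
    else:
        raise ValueError(f"unknown layer {layer!r}")
    return float(u[:, :, mask].mean())


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

class FlowSolver:
    """Projection solver for the cilia-driven two-layer ASL flow."""

    def __init__(self, grid: GridSpec, fluid: FluidProps | None = None, *,
                 giesekus: GiesekusParams | None = None,
                 markers: MarkerField | None = None,
                 dt: float | None = None, n_force_iter: int = 2,
                 bottom_wall_velocity=None,
                 divergence_tol: float = 1e-8):
        self.grid = grid
        self.fluid = fluid or FluidProps()
        self.giesekus = giesekus
        self.markers = markers
        self.n_force_iter = n_force_iter
        self.bottom_wall_velocity = bottom_wall_velocity
        self.divergence_tol = divergence_tol
        period = 1.0 / markers.lattice.frequency if markers else 1.0 / 15.0
        self.dt = dt or period / 2000.0
        self._lam_xy = _lateral_eigenvalues(grid)
        self._mask = grid.mucus_mask()

    # -- state ------------------------------------------------------------

    def initial_state(self) -> FlowState:
        u, v, w = self.grid.velocity_fields()
        tau = None
        if self.giesekus is not None:
            tau = np.zeros((self.giesekus.n_modes, 6) + self.grid.shape)
        return FlowState(u=u, v=v, w=w, p=self.grid.scalar_field(), tau=tau)

    # -- spatial operators -------------------------------------------------

    def _wall_uv(self, t: float) -> tuple[float, float]:
        if self.bottom_wall_velocity is None:
            return 0.0, 0.0
        return self.bottom_wall_velocity(t)

    def _center_velocity(self, u, v, w):
        uc = 0.5 * (u + np.roll(u, -1, axis=0))
        vc = 0.5 * (v + np.roll(v, -1, axis=1))
        wc = 0.5 * (w[:, :, :-1] + w[:, :, 1:])
        return uc, vc, wc

    def _velocity_gradient(self, u, v, w, t: float):
        """L[i][j] = du_i/dx_j at cell centres (ghost-consistent in z)."""
        d = self.grid.dx
        uwall, vwall = self._wall_uv(t)
        uc, vc, wc = self._center_velocity(u, v, w)
        L = [[None] * 3 for _ in range(3)]
        L[0][0] = (np.roll(u, -1, axis=0) - u) / d
        L[1][1] = (np.roll(v, -1, axis=1) - v) / d
        L[2][2] = (w[:, :, 1:] - w[:, :, :-1]) / d

        def ddy(f):
            return (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2 * d)

        def ddx(f):
            return (np.roll(f, -1, axis=0) - np.roll(f, 1, axis=0)) / (2 * d)

        def ddz(f, bottom, wall=0.0):
            fp = _pad_z_centered(f, bottom, "freeslip", wall)
            return (fp[:, :, 2:] - fp[:, :, :-2]) / (2 * d)

        L[0][1] = ddy(uc)
        L[0][2] = ddz(uc, "noslip", uwall)
        L[1][0] = ddx(vc)
        L[1][2] = ddz(vc, "noslip", vwall)
        L[2][0] = ddx(wc)
        L[2][1] = ddy(wc)
        return L

    def _advection(self, u, v, w):
        """Conservative advection terms for (u, v, w) on their faces."""
        d = self.grid.dx
        uc, vc, wc = self._center_velocity(u, v, w)

        # --- x momentum (u faces) ---
        duu = (uc**2 - np.roll(uc**2, 1, axis=0)) / d
        u_at_xy = 0.5 * (u + np.roll(u, 1, axis=1))          # corners (i, j)
        v_at_xy = 0.5 * (v + np.roll(v, 1, axis=0))
        duv = (np.roll(u_at_xy * v_at_xy, -1, axis=1)
               - u_at_xy * v_at_xy) / d
        u_at_xz = np.zeros((self.grid.nx, self.grid.ny, self.grid.nz + 1))
        u_at_xz[:, :, 1:-1] = 0.5 * (u[:, :, 1:] + u[:, :, :-1])
        w_at_xz = 0.5 * (w + np.roll(w, 1, axis=0))
        uw = u_at_xz * w_at_xz                                # zero on walls
        duw = (uw[:, :, 1:] - uw[:, :, :-1]) / d
        adv_u = duu + duv + duw

        # --- y momentum (v faces) ---
        dvv = (vc**2 - np.roll(vc**2, 1, axis=1)) / d
        duv2 = (np.roll(u_at_xy * v_at_xy, -1, axis=0)
                - u_at_xy * v_at_xy) / d
        v_at_yz = np.zeros_like(u_at_xz)
        v_at_yz[:, :, 1:-1] = 0.5 * (v[:, :, 1:] + v[:, :, :-1])
        w_at_yz = 0.5 * (w + np.roll(w, 1, axis=1))
        vw = v_at_yz * w_at_yz
        dvw = (vw[:, :, 1:] - vw[:, :, :-1]) / d
        adv_v = dvv + duv2 + dvw

        # --- z momentum (w faces, interior only) ---
        adv_w = np.zeros_like(w)
        dww = (wc[:, :, 1:]**2 - wc[:, :, :-1]**2) / d
        duw2 = (np.roll(uw, -1, axis=0) - uw) / d
        dvw2 = (np.roll(vw, -1, axis=1) - vw) / d
        adv_w[:, :, 1:-1] = dww + duw2[:, :, 1:-1] + dvw2[:, :, 1:-1]
        return adv_u, adv_v, adv_w

    def _stress_divergence(self, tau_sum):
        """(div tau) on the velocity faces from cell-centred tau (Pa)."""
        d = self.grid.dx
        xx, yy, zz, xy, xz, yz = tau_sum

        def corner_xy(f):
            return 0.25 * (f + np.roll(f, 1, axis=0) + np.roll(f, 1, axis=1)
                           + np.roll(np.roll(f, 1, axis=0), 1, axis=1))

        def zedges_from(f_face):
            """Values on z-edges (k = 0..nz) from z-centred values on a face
            column; the stress vanishes at both walls (PCL below, air above)."""
            e = np.zeros(f_face.shape[:2] + (f_face.shape[2] + 1,))
            e[:, :, 1:-1] = 0.5 * (f_face[:, :, 1:] + f_face[:, :, :-1])
            return e

        # x momentum
        dxx = (xx - np.roll(xx, 1, axis=0)) / d
        cxy = corner_xy(xy)
        dxy = (np.roll(cxy, -1, axis=1) - cxy) / d
        xz_face = 0.5 * (xz + np.roll(xz, 1, axis=0))
        exz = zedges_from(xz_face)
        dxz = (exz[:, :, 1:] - exz[:, :, :-1]) / d
        fx = dxx + dxy + dxz

        # y momentum
        dyy = (yy - np.roll(yy, 1, axis=1)) / d
        dyx = (np.roll(cxy, -1, axis=0) - cxy) / d
        yz_face = 0.5 * (yz + np.roll(yz, 1, axis=1))
        eyz = zedges_from(yz_face)
        dyz = (eyz[:, :, 1:] - eyz[:, :, :-1]) / d
        fy = dyy + dyx + dyz

        # z momentum (interior faces)
        fz = np.zeros((self.grid.nx, self.grid.ny, self.grid.nz + 1))
        fz[:, :, 1:-1] = (zz[:, :, 1:] - zz[:, :, :-1]) / d
        # d(tau_xz)/dx at the w face: average xz to z-edges in its own column
        exz2 = zedges_from(xz)
        fz[:, :, 1:-1] += ((np.roll(exz2, -1, axis=0)
                            - np.roll(exz2, 1, axis=0)) / (2 * d))[:, :, 1:-1]
        eyz2 = zedges_from(yz)
        fz[:, :, 1:-1] += ((np.roll(eyz2, -1, axis=1)
                            - np.roll(eyz2, 1, axis=1)) / (2 * d))[:, :, 1:-1]
        return fx, fy, fz

    def _stress_advect_op(self, uc, vc, wc):
        d = self.grid.dx

        def op(f):
            out = uc * (np.roll(f, -1, axis=0) - np.roll(f, 1, axis=0)) / (2 * d)
            out += vc * (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2 * d)
            fp = _pad_z_centered(f, "zero", "zero")
            out += wc * (fp[:, :, 2:] - fp[:, :, :-2]) / (2 * d)
            return out

        return op

    # -- implicit solves ---------------------------------------------------

    def _helmholtz_uv(self, rhs, a):
        """Solve (1 - a lap) x = rhs for a z-centred field (no-slip bottom,
        free-slip top); ``a = dt * nu``."""
        d2 = self.grid.dx**2
        r = np.fft.rfft2(rhs, axes=(0, 1))
        nz = self.grid.nz
        diag = np.empty(r.shape, dtype=float)
        diag[...] = 1.0 - a * self._lam_xy[:, :, None] + 2.0 * a / d2
        diag[..., 0] += a / d2   # antisymmetric ghost: -3 coefficient
        diag[..., -1] -= a / d2  # symmetric ghost: -1 coefficient
        x = _thomas(diag, -a / d2, -a / d2, r)
        return np.fft.irfft2(x, s=rhs.shape[:2], axes=(0, 1))

    def _helmholtz_w(self, rhs, a):
        """Same for the z-face field w (Dirichlet 0 on both walls)."""
        d2 = self.grid.dx**2
        interior = rhs[:, :, 1:-1]
        r = np.fft.rfft2(interior, axes=(0, 1))
        diag = np.empty(r.shape, dtype=float)
        diag[...] = 1.0 - a * self._lam_xy[:, :, None] + 2.0 * a / d2
        x = _thomas(diag, -a / d2, -a / d2, r)
        out = np.zeros_like(rhs)
        out[:, :, 1:-1] = np.fft.irfft2(x, s=interior.shape[:2], axes=(0, 1))
        return out

    def _pressure_poisson(self, div):
        """Solve lap phi = div with Neumann z walls, periodic x'/y'."""
        d2 = self.grid.dx**2
        r = np.fft.rfft2(div, axes=(0, 1))
        diag = np.empty(r.shape, dtype=float)
        diag[...] = self._lam_xy[:, :, None] - 2.0 / d2
        diag[..., 0] += 1.0 / d2
        diag[..., -1] += 1.0 / d2
        # Zero lateral mode: the pure-Neumann column is singular (constant
        # nullspace).  Remove the rhs mean (compatibility) and perturb the
        # first row; because the Neumann rows telescope, the perturbed solve
        # returns the exact mean-grounded solution of the original system.
        r[0, 0] -= r[0, 0].mean()
        diag[0, 0, 0] -= 1.0 / d2
        x = _thomas(diag, 1.0 / d2, 1.0 / d2, r)
        phi = np.fft.irfft2(x, s=div.shape[:2], axes=(0, 1))
        return phi - phi.mean()

    # -- time step ---------------------------------------------------------

    def step(self, state: FlowState) -> FlowState:
        grid, dt, rho = self.grid, self.dt, self.fluid.density
        d = grid.dx
        u, v, w = state.u, state.v, state.w
        umax = max(np.abs(u).max(), np.abs(v).max(), np.abs(w).max())
        if umax * dt / d > 0.8:
            raise RuntimeError(
                f"advective CFL violation: |u|max dt/dx = {umax * dt / d:.2f}; "
                f"reduce dt below {0.5 * d / umax:.3e} s")

        # 1. constitutive update (mucus layer only)
        if state.tau is not None:
            L = self._velocity_gradient(u, v, w, state.t)
            uc, vc, wc = self._center_velocity(u, v, w)
            state.tau = giesekus_update(
                state.tau, L, dt, self.giesekus,
                advect=self._stress_advect_op(uc, vc, wc), mask=self._mask)
            fx, fy, fz = self._stress_divergence(state.tau.sum(axis=0))
        else:
            fx = fy = fz = 0.0

        # 2. predictor with implicit solvent diffusion
        adv_u, adv_v, adv_w = self._advection(u, v, w)
        a = dt * self.fluid.nu
        rhs_u = u + dt * (-adv_u + fx / rho)
        rhs_v = v + dt * (-adv_v + fy / rho)
        rhs_w = w + dt * (-adv_w + fz / rho)
        uwall, vwall = self._wall_uv(state.t + dt)
        if uwall or vwall:
            rhs_u[:, :, 0] += 2.0 * a / d**2 * uwall
            rhs_v[:, :, 0] += 2.0 * a / d**2 * vwall
        us = self._helmholtz_uv(rhs_u, a)
        vs = self._helmholtz_uv(rhs_v, a)
        ws = self._helmholtz_w(rhs_w, a)

        # 3. direct forcing at the cilium markers
        if self.markers is not None:
            mk = self.markers.markers_at(state.t + dt)
            dV_f = mk.dV if mk.dV_force is None else mk.dV_force
            for _ in range(max(1, self.n_force_iter)):
                u_mk = interpolate_velocity(us, vs, ws, mk.X, grid)
                F = (mk.U - u_mk) / dt
                gu, gv, gw = spread_force(F, dV_f, mk.X, grid)
                us = us + dt * gu
                vs = vs + dt * gv
                ws = ws + dt * gw
            self._last_forcing_residual = float(
                np.abs(mk.U - interpolate_velocity(us, vs, ws, mk.X, grid)).max())

        # 4. projection
        div = divergence(us, vs, ws, grid)
        phi = self._pressure_poisson(div)
        us -= (phi - np.roll(phi, 1, axis=0)) / d
        vs -= (phi - np.roll(phi, 1, axis=1)) / d
        ws[:, :, 1:-1] -= (phi[:, :, 1:] - phi[:, :, :-1]) / d
        state.u, state.v, state.w = us, vs, ws
        state.p = rho / dt * phi
        state.t += dt
        apply_flow_bcs(state, grid)

        res = np.abs(divergence(us, vs, ws, grid)).max()
        scale = max(umax / d, 1e-12)
        if res > max(self.divergence_tol * scale, 1e-12):
            raise RuntimeError(f"projection failed: max |div u| = {res:.3e}")
        return state

    # -- cycle recording ---------------------------------------------------

    def run_cycles(self, state: FlowState, n_cycles: float,
                   record: int = 0) -> "CycleReplay | FlowState":
        """Advance ``n_cycles`` beat cycles; optionally record the last one.

        With ``record > 0`` the final cycle is sampled at ``record`` equally
        spaced instants and returned as a :class:`CycleReplay` (the one-way
        coupled transport solver replays it periodically).
        """
        period = (1.0 / self.markers.lattice.frequency if self.markers
                  else 2000 * self.dt)
        steps_per_cycle = max(1, round(period / self.dt))
        total = round(n_cycles * steps_per_cycle)
        rec_steps = []
        if record:
            every = max(1, steps_per_cycle // record)
            rec_steps = [total - steps_per_cycle + i * every
                         for i in range(record)]
        snaps = []
        times = []
        for i in range(total):
            if i in rec_steps:
                snaps.append((state.u.copy(), state.v.copy(), state.w.copy()))
                times.append(state.t)
            state = self.step(state)
        if record:
            return CycleReplay(np.array([s[0] for s in snaps]),
                               np.array([s[1] for s in snaps]),
                               np.array([s[2] for s in snaps]),
                               t0=times[0], period=period)
        return state


class CycleReplay:
    """One recorded beat cycle of velocity snapshots, replayed periodically.

    One-way coupling makes this exact up to the time-interpolation error:
    after spin-up the flow is T_c-periodic, so long transport episodes can
    reuse a single converged cycle.
    """

    def __init__(self, u, v, w, t0: float, period: float):
        self.u, self.v, self.w = u, v, w
        self.t0 = t0
        self.period = period
        self.n = u.shape[0]

    def velocity_at(self, t: float):
        s = ((t - self.t0) / self.period * self.n) % self.n
        i0 = int(s) % self.n
        i1 = (i0 + 1) % self.n
        f = s - int(s)
        return ((1 - f) * self.u[i0] + f * self.u[i1],
                (1 - f) * self.v[i0] + f * self.v[i1],
                (1 - f) * self.w[i0] + f * self.w[i1])

    def mean_speed(self) -> float:
        return float(np.mean(np.abs(self.u)))
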