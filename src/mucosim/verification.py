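"""Built-in analytic benchmarks and miniature property fixtures.

The transport discretization (three-substep Runge-Kutta in time, second-order
central differences in space) is verified against the one-dimensional
convection-diffusion problem

    dc/dt + kappa dc/dx = beta d2c/dx2,   x in [0, 1],

with advection speed ``kappa = 0.8``, diffusivity ``beta = 0.1``, Gaussian
initial condition ``g(x) = exp(-(x - 2)^2 / 8)`` and time-dependent Dirichlet
boundary data taken from the exact solution

    c(x, t) = sqrt(20 / (20 + t)) * exp(-(x - 2 - 0.8 t)^2 / (0.4 (t + 20))),

the spreading, advecting Gaussian.  The solver must reproduce it to a maximum
relative error of a few 1e-6 at a (reported) resolution, and the error must
fall off with the square of the grid spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transport import RK3_GAMMA, RK3_STAGE_TIME, RK3_ZETA

__all__ = ["AnalyticCaseSpec", "exact_solution", "solve_analytic_case",
           "verify_analytic", "convergence_slope", "make_fixture"]


@dataclass(frozen=True)
class AnalyticCaseSpec:
    """Parameters of the 1-D convection-diffusion benchmark."""

    kappa: float = 0.8
    beta: float = 0.1
    x_min: float = 0.0
    x_max: float = 1.0

    def initial_condition(self, x):
        return np.exp(-((x - 2.0) ** 2) / 8.0)

    def h0(self, t):
        """Left boundary value c(0, t)."""
        return np.sqrt(20.0 / (20.0 + t)) \
            * np.exp(-2.0 * (5.0 + 2.0 * t) ** 2 / (5.0 * (t + 20.0)))

    def h1(self, t):
        """Right boundary value c(1, t)."""
        return np.sqrt(20.0 / (20.0 + t)) \
            * np.exp(-((5.0 + 4.0 * t) ** 2) / (10.0 * (t + 20.0)))


def exact_solution(x, t, spec: AnalyticCaseSpec | None = None):
    """Exact solution of the benchmark (advecting, spreading Gaussian)."""
    return np.sqrt(20.0 / (20.0 + t)) \
        * np.exp(-((x - 2.0 - 0.8 * t) ** 2) / (0.4 * (t + 20.0)))


def solve_analytic_case(n_cells: int, t_end: float, dt: float | None = None,
                        spec: AnalyticCaseSpec | None = None):
    """Integrate the benchmark with the production RK3/central kernel.

    Node-based 1-D grid (endpoints carry the Dirichlet data, imposed at the
    RK stage times).  Returns ``(x, c_numeric, c_exact, max_rel_error)``
    where the relative error is normalised by the peak exact value on the
    domain.

    ``dt`` defaults to a quarter of the diffusive stability limit so the
    temporal error (third order) is negligible against the spatial error.
    """
    spec = spec or AnalyticCaseSpec()
    x = np.linspace(spec.x_min, spec.x_max, n_cells + 1)
    dx = x[1] - x[0]
    if dt is None:
        dt = 0.25 * dx**2 / spec.beta
    c = spec.initial_condition(x)
    n_steps = int(np.ceil(t_end / dt))
    dt = t_end / n_steps

    def rhs(ci):
        out = np.zeros_like(ci)
        out[1:-1] = (-spec.kappa * (ci[2:] - ci[:-2]) / (2.0 * dx)
                     + spec.beta * (ci[2:] - 2.0 * ci[1:-1] + ci[:-2]) / dx**2)
        return out

    t = 0.0
    for _ in range(n_steps):
        if not np.all(np.isfinite(c)):
            raise FloatingPointError("analytic benchmark went unstable; "
                                     "reduce dt")
        r_prev = None
        for s in range(3):
            r = rhs(c)
            c = c + dt * RK3_GAMMA[s] * r
            if s and r_prev is not None:
                c = c + dt * RK3_ZETA[s] * r_prev
            t_stage = t + RK3_STAGE_TIME[s] * dt
            c[0] = spec.h0(t_stage)
            c[-1] = spec.h1(t_stage)
            r_prev = r
        t += dt
    exact = exact_solution(x, t_end)
    err = float(np.max(np.abs(c - exact)) / np.max(np.abs(exact)))
    return x, c, exact, err


def verify_analytic(tolerance: float = 3.5e-6,
                    times=(0.1, 0.4, 0.8), n_start: int = 64,
                    n_max: int = 4096):
    """Double the resolution until the benchmark meets ``tolerance``.

    Returns ``(n_cells, worst_error)`` over the requested sample times.
    Raises if the tolerance is still unmet at ``n_max``.
    """
    n = n_start
    while True:
        worst = max(solve_analytic_case(n, t)[3] for t in times)
        if worst <= tolerance:
            return n, worst
        if n >= n_max:
            raise RuntimeError(
                f"benchmark error {worst:.2e} above {tolerance:.1e} at "
                f"n = {n}")
        n *= 2


def convergence_slope(resolutions=(32, 64, 128), t_end: float = 0.4) -> float:
    """Log-log slope of the benchmark error versus grid spacing."""
    errs = [solve_analytic_case(n, t_end)[3] for n in resolutions]
    h = 1.0 / np.asarray(resolutions, dtype=float)
    slope = np.polyfit(np.log(h), np.log(errs), 1)[0]
    return float(slope)


def make_fixture(preset: str) -> dict:
    """Deterministic miniature configurations with checkable properties.

    Presets
    -------
    ``column-1d``
        Quiescent diffusion column; steady linear profile under constant
        influx, deposition rate equal to the influx.
    ``tiny-flow``
        Small strip, no cilia: quiescence is preserved.
    ``single-cilium``
        One cilium on a coarse strip: the cycle-averaged mucus-layer
        velocity must be positive (propulsion towards +x').
    ``tiny-transport``
        Coarse strip with a few cilia for attachment/ledger property runs.
    """
    presets = {
        "column-1d": {
            "grid": dict(nx=1, ny=1, nz=32),
            "expect": ["linear_steady_profile", "deposition_equals_influx"],
        },
        "tiny-flow": {
            "grid": dict(nx=16, ny=4, nz=12),
            "cilia": None,
            "expect": ["quiescence_preserved", "divergence_free"],
        },
        "single-cilium": {
            "grid": dict(nx=24, ny=4, nz=16),
            "cilia": dict(count=1),
            "cycles": 2,
            "expect": ["positive_mean_mucus_velocity", "divergence_free"],
        },
        "tiny-transport": {
            "grid": dict(nx=32, ny=4, nz=16),
            "cilia": dict(count=16),
            "expect": ["mass_budget_closure", "car_zero_without_attachment"],
        },
    }
    try:
        return presets[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; "
                         f"choose from {sorted(presets)}") from None
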