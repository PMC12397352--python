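"""Multi-mode Giesekus viscoelastic stress for the mucus layer.

Mucus is modelled as a 5-mode nonlinear Giesekus fluid on top of a Newtonian
solvent contribution.  Each mode carries a symmetric extra-stress tensor
``tau_a`` obeying

    tau_a + lambda_a * UCD(tau_a) + (alpha_a lambda_a / eta_a) tau_a.tau_a
        = 2 eta_a D,

where ``UCD`` is the upper-convected derivative

    UCD(tau) = d tau/dt + u.grad tau - L.tau - tau.L^T,   L_ij = du_i/dx_j,

``D = (L + L^T)/2`` the rate of strain, ``lambda_a`` the relaxation time (s),
``eta_a`` the modal elastic viscosity (Pa s) and ``alpha_a`` in [0, 1] the
mobility parameter controlling shear thinning (alpha = 0 recovers the
upper-convected Maxwell model).

The default coefficient set is the published 5-mode fit to cultured human
bronchial epithelial mucus in the healthy state.

Stress tensors are cell-centred.  Symmetric tensors are stored as arrays of
shape ``(6,) + grid`` in Voigt-like order (xx, yy, zz, xy, xz, yz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GiesekusParams", "HBE_MUCUS_MODES", "giesekus_update",
           "steady_shear_ucm", "steady_shear_giesekus", "tensor_dot_sym"]

#: (relaxation time s, elastic viscosity Pa s, mobility) per mode -- healthy
#: cultured human bronchial epithelial mucus, 5-mode fit.
HBE_MUCUS_MODES = (
    (0.0089, 0.0298, 0.20),
    (0.0821, 0.0620, 0.30),
    (0.4660, 0.2493, 0.50),
    (3.1290, 1.4215, 0.50),
    (49.7334, 2.2034, 0.50),
)

_XX, _YY, _ZZ, _XY, _XZ, _YZ = range(6)


@dataclass(frozen=True)
class GiesekusParams:
    """Per-mode Giesekus coefficients."""

    lambdas: tuple[float, ...]
    etas: tuple[float, ...]
    alphas: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.lambdas)
        if not (len(self.etas) == len(self.alphas) == n):
            raise ValueError("mode arrays must have equal length")
        if any(l <= 0 for l in self.lambdas) or any(e <= 0 for e in self.etas):
            raise ValueError("relaxation times and viscosities must be positive")
        if any(not 0.0 <= a <= 1.0 for a in self.alphas):
            raise ValueError("mobility parameters must lie in [0, 1]")

    @property
    def n_modes(self) -> int:
        return len(self.lambdas)

    @property
    def total_elastic_viscosity(self) -> float:
        return float(sum(self.etas))

    @classmethod
    def hbe_mucus(cls) -> "GiesekusParams":
        lam, eta, alp = zip(*HBE_MUCUS_MODES)
        return cls(lam, eta, alp)

    @classmethod
    def single_mode(cls, lam: float, eta: float, alpha: float) -> "GiesekusParams":
        return cls((lam,), (eta,), (alpha,))


def tensor_dot_sym(t: np.ndarray) -> np.ndarray:
    """``tau . tau`` of a symmetric tensor in (xx,yy,zz,xy,xz,yz) storage."""
    xx, yy, zz, xy, xz, yz = t
    return np.stack([
        xx * xx + xy * xy + xz * xz,
        xy * xy + yy * yy + yz * yz,
        xz * xz + yz * yz + zz * zz,
        xx * xy + xy * yy + xz * yz,
        xx * xz + xy * yz + xz * zz,
        xy * xz + yy * yz + yz * zz,
    ])


def _lt_plus_tlT(L: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Symmetric part source ``L.tau + tau.L^T`` (result is symmetric)."""
    xx, yy, zz, xy, xz, yz = t
    l = L  # L[i, j] = du_i/dx_j, each entry a field
    out_xx = 2.0 * (l[0][0] * xx + l[0][1] * xy + l[0][2] * xz)
    out_yy = 2.0 * (l[1][0] * xy + l[1][1] * yy + l[1][2] * yz)
    out_zz = 2.0 * (l[2][0] * xz + l[2][1] * yz + l[2][2] * zz)
    out_xy = (l[0][0] + l[1][1]) * xy + l[0][1] * yy + l[0][2] * yz \
        + l[1][0] * xx + l[1][2] * xz
    out_xz = (l[0][0] + l[2][2]) * xz + l[0][1] * yz + l[0][2] * zz \
        + l[2][0] * xx + l[2][1] * xy
    out_yz = (l[1][1] + l[2][2]) * yz + l[1][0] * xz + l[1][2] * zz \
        + l[2][0] * xy + l[2][1] * yy
    return np.stack([out_xx, out_yy, out_zz, out_xy, out_xz, out_yz])


def rate_of_strain(L: np.ndarray) -> np.ndarray:
    """Symmetric rate of strain ``D = (L + L^T)/2`` in 6-component storage."""
    return np.stack([
        L[0][0], L[1][1], L[2][2],
        0.5 * (L[0][1] + L[1][0]),
        0.5 * (L[0][2] + L[2][0]),
        0.5 * (L[1][2] + L[2][1]),
    ])


def giesekus_update(tau: np.ndarray, L, dt: float, params: GiesekusParams,
                    advect=None, mask: np.ndarray | None = None) -> np.ndarray:
    """Explicit-Euler update of the per-mode stresses over ``dt``.

    Parameters
    ----------
    tau
        Modal stresses, shape ``(n_modes, 6) + grid``.
    L
        Velocity gradient as a nested 3x3 sequence of fields,
        ``L[i][j] = du_i/dx_j``.
    advect
        Optional callable ``advect(component_field) -> u.grad field`` for the
        advective term of the upper-convected derivative; omitted (= 0) for
        homogeneous problems.
    mask
        Optional boolean field: stress is hard-zeroed where False (the PCL
        and the air-mucus interface are Newtonian, tau = 0).

    Returns the updated stresses; symmetry is preserved exactly because only
    symmetric combinations are formed.  Raises ``FloatingPointError`` when the
    update produces non-finite stress (stability failure).
    """
    D = rate_of_strain(L)
    out = np.empty_like(tau)
    err = np.errstate(over="ignore", invalid="ignore")  # caught below
    err.__enter__()
    for a in range(params.n_modes):
        lam, eta, alp = params.lambdas[a], params.etas[a], params.alphas[a]
        t = tau[a]
        rhs = (2.0 * eta * D - t - (alp * lam / eta) * tensor_dot_sym(t)) / lam
        rhs = rhs + _lt_plus_tlT(L, t)
        if advect is not None:
            rhs = rhs - np.stack([advect(t[c]) for c in range(6)])
        out[a] = t + dt * rhs
    err.__exit__(None, None, None)
    if not np.all(np.isfinite(out)):
        wi = max(params.lambdas) * float(np.max(np.abs(np.asarray(
            [[np.max(np.abs(L[i][j])) for j in range(3)] for i in range(3)]))))
        raise FloatingPointError(
            f"Giesekus update produced non-finite stress (dt={dt:.3e}, "
            f"Weissenberg estimate {wi:.3e}); reduce dt")
    if mask is not None:
        out *= mask
    return out


# ---------------------------------------------------------------------------
# Steady simple-shear references (oracles for tests)
# ---------------------------------------------------------------------------

def steady_shear_ucm(lam: float, eta: float, gamma_dot: float):
    """Closed-form steady simple-shear stress of one UCM mode (alpha = 0).

    For ``u = (gamma_dot * z, 0, 0)``:  ``tau_xz = eta gamma_dot`` and
    ``tau_xx = 2 eta lam gamma_dot^2``; all other components vanish.
    """
    return {"xx": 2.0 * eta * lam * gamma_dot**2, "xz": eta * gamma_dot,
            "zz": 0.0}


def steady_shear_giesekus(lam: float, eta: float, alpha: float,
                          gamma_dot: float):
    """Steady simple-shear stress of one Giesekus mode via a nonlinear solve.

    Independent algebraic reference: solves the 3-equation steady-state
    system for (tau_xx, tau_zz, tau_xz) in shear ``u = (gamma_dot z, 0, 0)``
    with ``scipy.optimize.fsolve``, seeded from the UCM solution.
    """
    from scipy.optimize import fsolve

    k = alpha * lam / eta

    def eqs(v):
        xx, zz, xz = v
        return [
            xx + k * (xx * xx + xz * xz) - 2.0 * lam * gamma_dot * xz,
            zz + k * (zz * zz + xz * xz),
            xz + k * xz * (xx + zz) - eta * gamma_dot - lam * gamma_dot * zz,
        ]

    ucm = steady_shear_ucm(lam, eta, gamma_dot)
    sol, info, ier, msg = fsolve(eqs, [ucm["xx"] * 0.5, -0.1 * ucm["xz"],
                                       ucm["xz"] * 0.5], full_output=True)
    if ier != 1:
        raise RuntimeError(f"steady-shear solve failed: {msg}")
    return {"xx": sol[0], "zz": sol[1], "xz": sol[2]}
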