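"""Regularized-delta interpolation and spreading (immersed-boundary kernel).

This module is the bridge between the Eulerian staggered grid and the
Lagrangian surface markers of the cilia, shared by the flow solver (velocity
interpolation / force spreading) and the transport solver (concentration
interpolation / mass-source spreading).

The kernel is the 3-point regularized Dirac delta of Roma, Peskin & Berger:
continuous, supported on ``|r| <= 1.5`` grid cells, and a partition of unity
(``sum_i phi(r - i) = 1`` for every real r), which makes spreading exactly
conservative:  ``sum_ijk q * dx^3 == sum_l Q_l * dV_l`` to round-off.

Axis handling: x' and y' wrap periodically; along z the stencil legs that
would fall outside the wall are folded onto the nearest valid plane.  Folding
preserves the partition of unity (interpolation of a constant stays exact)
and conservation (no spread mass is lost), at the cost of reduced accuracy in
the half-cell next to each wall -- cilium base markers are the only users.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GridSpec

__all__ = ["phi", "DeltaKernel", "interpolate_scalar", "spread_scalar",
           "interpolate_velocity", "spread_force"]

_OFFSETS = np.array([-1, 0, 1])


def phi(r):
    """Roma 3-point kernel weight for a dimensionless offset ``r``.

    Piecewise:
      * ``|r| <= 0.5``        : ``(1 + sqrt(1 - 3 r^2)) / 3``
      * ``0.5 <= |r| <= 1.5`` : ``(5 - 3|r| - sqrt(1 - 3 (1 - |r|)^2)) / 6``
      * otherwise             : 0
    """
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    inner = r <= 0.5
    mid = (r > 0.5) & (r <= 1.5)
    out[inner] = (1.0 + np.sqrt(np.maximum(1.0 - 3.0 * r[inner] ** 2, 0.0))) / 3.0
    rm = r[mid]
    out[mid] = (5.0 - 3.0 * rm
                - np.sqrt(np.maximum(1.0 - 3.0 * (1.0 - rm) ** 2, 0.0))) / 6.0
    return out


@dataclass(frozen=True)
class DeltaKernel:
    """3-point regularized delta on a uniform grid of spacing ``dx``."""

    dx: float
    support: float = 1.5

    def weights(self, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Stencil indices and weights along one axis.

        Parameters
        ----------
        g
            Marker coordinates in index space of the target variable
            (i.e. ``x/dx`` already shifted for staggering), shape ``(n,)``.

        Returns
        -------
        idx : ``(n, 3)`` integer stencil indices (unwrapped).
        w   : ``(n, 3)`` kernel weights; rows sum to 1.
        """
        i0 = np.rint(g).astype(int)
        idx = i0[:, None] + _OFFSETS[None, :]
        w = phi(g[:, None] - idx)
        return idx, w


def _axis_indices(x: np.ndarray, dx: float, n: int, *, staggered: bool,
                  periodic: bool, fold_lo: int = 0, fold_hi: int | None = None):
    """Index/weight pairs for one axis with wrap or wall folding."""
    g = x / dx if staggered else x / dx - 0.5
    idx, w = DeltaKernel(dx).weights(g)
    if periodic:
        idx = np.mod(idx, n)
    else:
        hi = (n - 1) if fold_hi is None else fold_hi
        idx = np.clip(idx, fold_lo, hi)
    return idx, w


def _gather(field, ix, iy, iz, wx, wy, wz):
    cube = field[ix[:, :, None, None], iy[:, None, :, None], iz[:, None, None, :]]
    return np.einsum("na,nb,nc,nabc->n", wx, wy, wz, cube)


def _scatter(field, vals, ix, iy, iz, wx, wy, wz):
    contrib = np.einsum("n,na,nb,nc->nabc", vals, wx, wy, wz)
    ny, nz = field.shape[1], field.shape[2]
    flat = ((ix[:, :, None, None] * ny + iy[:, None, :, None]) * nz
            + iz[:, None, None, :])
    field += np.bincount(flat.ravel(), weights=contrib.ravel(),
                         minlength=field.size).reshape(field.shape)


def _cc_stencil(points: np.ndarray, grid: GridSpec):
    ix, wx = _axis_indices(points[:, 0], grid.dx, grid.nx,
                           staggered=False, periodic=True)
    iy, wy = _axis_indices(points[:, 1], grid.dx, grid.ny,
                           staggered=False, periodic=True)
    iz, wz = _axis_indices(points[:, 2], grid.dx, grid.nz,
                           staggered=False, periodic=False)
    return ix, iy, iz, wx, wy, wz


def interpolate_scalar(field: np.ndarray, points: np.ndarray,
                       grid: GridSpec) -> np.ndarray:
    """Interpolate a cell-centred scalar to marker positions.

    Implements ``C_l = sum_ijk c delta_d(x_ijk - X_l) dx dy dz`` (the delta
    carries a ``1/dx^3`` which cancels the cell volume, so the weights are the
    bare tensor-product kernel values).
    """
    pts = np.atleast_2d(points)
    return _gather(field, *_cc_stencil(pts, grid))


def spread_scalar(values: np.ndarray, dV: np.ndarray, points: np.ndarray,
                  grid: GridSpec, out: np.ndarray | None = None) -> np.ndarray:
    """Spread per-marker sources ``Q_l`` (with element volumes ``dV_l``) to a
    cell-centred field:  ``q_ijk = sum_l Q_l delta_d(x_ijk - X_l) dV_l``.
    """
    pts = np.atleast_2d(points)
    q = grid.scalar_field() if out is None else out
    ix, iy, iz, wx, wy, wz = _cc_stencil(pts, grid)
    scaled = np.asarray(values, dtype=float) * np.asarray(dV, dtype=float) \
        / grid.cell_volume
    _scatter(q, scaled, ix, iy, iz, wx, wy, wz)
    return q


def _face_stencil(points: np.ndarray, grid: GridSpec, component: str):
    """Stencil for a staggered velocity component ('u', 'v' or 'w')."""
    d = grid.dx
    if component == "u":
        ix, wx = _axis_indices(points[:, 0], d, grid.nx, staggered=True,
                               periodic=True)
        iy, wy = _axis_indices(points[:, 1], d, grid.ny, staggered=False,
                               periodic=True)
        iz, wz = _axis_indices(points[:, 2], d, grid.nz, staggered=False,
                               periodic=False)
    elif component == "v":
        ix, wx = _axis_indices(points[:, 0], d, grid.nx, staggered=False,
                               periodic=True)
        iy, wy = _axis_indices(points[:, 1], d, grid.ny, staggered=True,
                               periodic=True)
        iz, wz = _axis_indices(points[:, 2], d, grid.nz, staggered=False,
                               periodic=False)
    elif component == "w":
        ix, wx = _axis_indices(points[:, 0], d, grid.nx, staggered=False,
                               periodic=True)
        iy, wy = _axis_indices(points[:, 1], d, grid.ny, staggered=False,
                               periodic=True)
        # z-faces 0..nz; the wall faces carry w=0 and must not receive force,
        # so spreading folds onto the first interior faces.
        iz, wz = _axis_indices(points[:, 2], d, grid.nz + 1, staggered=True,
                               periodic=False, fold_lo=1, fold_hi=grid.nz - 1)
    else:  # pragma: no cover - internal misuse
        raise ValueError(component)
    return ix, iy, iz, wx, wy, wz


def interpolate_velocity(u: np.ndarray, v: np.ndarray, w: np.ndarray,
                         points: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Interpolate the staggered velocity to markers; returns ``(n, 3)``.

    Each component is interpolated at its own face locations so that the
    result is consistent with the projection discretization.
    """
    pts = np.atleast_2d(points)
    out = np.empty((pts.shape[0], 3))
    for k, (comp, fld) in enumerate((("u", u), ("v", v), ("w", w))):
        out[:, k] = _gather(fld, *_face_stencil(pts, grid, comp))
    return out


def spread_force(forces: np.ndarray, dV: np.ndarray, points: np.ndarray,
                 grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spread per-marker force densities ``F_l`` (n, 3) to the staggered grid."""
    pts = np.atleast_2d(points)
    fu, fv, fw = (np.zeros(grid.shape), np.zeros(grid.shape),
                  np.zeros((grid.nx, grid.ny, grid.nz + 1)))
    scale = np.asarray(dV, dtype=float) / grid.cell_volume
    for comp, fld, col in (("u", fu, 0), ("v", fv, 1), ("w", fw, 2)):
        ix, iy, iz, wx, wy, wz = _face_stencil(pts, grid, comp)
        _scatter(fld, forces[:, col] * scale, ix, iy, iz, wx, wy, wz)
    return fu, fv, fw
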