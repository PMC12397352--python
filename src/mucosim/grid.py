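"""Uniform staggered Cartesian grid for the airway-surface-liquid (ASL) domain.

The computational domain is the reduced (counter-diagonal) periodic strip of the
ciliated epithelium: periodic in x' and y', walls at z=0 (epithelium, no slip)
and z=L_z (air--mucus interface, free slip).  All quantities are SI (metres).

Staggering follows the usual MAC convention:

* ``u`` (x'-velocity) lives at x-faces, shape ``(nx, ny, nz)``; face i sits at
  ``x = i*dx`` between cell centres ``i-1`` and ``i`` (periodic wrap).
* ``v`` (y'-velocity) lives at y-faces, shape ``(nx, ny, nz)``.
* ``w`` (z-velocity) lives at z-faces, shape ``(nx, ny, nz+1)``; faces 0 and nz
  are the epithelium and the interface, where ``w = 0`` always.
* scalars (pressure, concentration, stress components) live at cell centres,
  shape ``(nx, ny, nz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "divergence", "cell_centers", "MESH_PRESETS"]

#: Mesh presets for the tracheal ASL strip (n_x' x n_y' x n_z).  M3 is the
#: reference mesh; M1/M2 are coarser, M4 finer.
MESH_PRESETS = {
    "M1": (300, 6, 131),
    "M2": (400, 8, 175),
    "M3": (500, 10, 219),
    "M4": (600, 12, 262),
}


@dataclass(frozen=True)
class GridSpec:
    """Uniform staggered grid over the ASL strip.

    Parameters
    ----------
    nx, ny, nz
        Cell counts along x', y' and z.
    lz
        Total ASL depth (m): PCL depth + mucus depth (default 7 + 10 um).
    z_interface
        PCL--mucus interface height (m).  Elastic stress is confined to
        ``z >= z_interface`` (the mucus layer); the PCL below is Newtonian.
    """

    nx: int
    ny: int
    nz: int
    lz: float = 17e-6
    z_interface: float = 7e-6

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0.0 < self.z_interface < self.lz:
            raise ValueError("z_interface must lie strictly inside (0, lz)")

    @property
    def dx(self) -> float:
        """Uniform spacing, ``lz / nz`` (dx = dy = dz)."""
        return self.lz / self.nz

    @property
    def lx(self) -> float:
        return self.nx * self.dx

    @property
    def ly(self) -> float:
        return self.ny * self.dx

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def cell_volume(self) -> float:
        return self.dx**3

    @property
    def top_area(self) -> float:
        """Area of the air--mucus interface of the strip."""
        return self.lx * self.ly

    def zc(self) -> np.ndarray:
        """z coordinates of cell centres."""
        return (np.arange(self.nz) + 0.5) * self.dx

    def zf(self) -> np.ndarray:
        """z coordinates of z-faces (0 .. lz)."""
        return np.arange(self.nz + 1) * self.dx

    def scalar_field(self) -> np.ndarray:
        return np.zeros(self.shape)

    def velocity_fields(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        u = np.zeros(self.shape)
        v = np.zeros(self.shape)
        w = np.zeros((self.nx, self.ny, self.nz + 1))
        return u, v, w

    def mucus_mask(self) -> np.ndarray:
        """Boolean cell-centre mask of the mucus layer (z >= z_interface)."""
        return self.zc() >= self.z_interface

    @classmethod
    def from_preset(cls, name: str, lz: float = 17e-6,
                    z_interface: float = 7e-6) -> "GridSpec":
        try:
            nx, ny, nz = MESH_PRESETS[name]
        except KeyError:
            raise ValueError(f"unknown mesh preset {name!r}; "
                             f"choose from {sorted(MESH_PRESETS)}") from None
        return cls(nx, ny, nz, lz=lz, z_interface=z_interface)


def cell_centers(grid: GridSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cell-centre coordinate vectors (xc, yc, zc)."""
    d = grid.dx
    xc = (np.arange(grid.nx) + 0.5) * d
    yc = (np.arange(grid.ny) + 0.5) * d
    return xc, yc, grid.zc()


def divergence(u: np.ndarray, v: np.ndarray, w: np.ndarray,
               grid: GridSpec) -> np.ndarray:
    """Discrete divergence at cell centres (periodic x', y'; w given on z-faces)."""
    d = grid.dx
    du = (np.roll(u, -1, axis=0) - u) / d
    dv = (np.roll(v, -1, axis=1) - v) / d
    dw = (w[:, :, 1:] - w[:, :, :-1]) / d
    return du + dv + dw
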