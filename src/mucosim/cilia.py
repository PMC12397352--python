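"""Cilium beat kinematics, metachronal lattice and Lagrangian surface markers.

Beat model
----------
Tracheal cilia beat with a two-stroke cycle: a fast *effective* stroke in
which the nearly straight cilium sweeps through the mucus in the clearance
direction (+x'), and a slower *recovery* stroke in which it bends backward
and low over the epithelium, minimising the retarding drag.  The classic
representation is a truncated Fourier series for the centreline position
versus (phase, arclength), fitted to rabbit-trachea observations.

The published coefficient table for that fit is not redistributable here, so
this module provides a **synthetic** beat with the same structure and the
properties that matter for mucociliary transport:

* the centreline is an *inextensible* planar curve of length ``L`` anchored at
  the origin, described by a tangent angle ``theta(s, phi)``;
* ``theta`` is stored as a truncated Fourier series in the beat phase ``phi``
  (so shape and velocity are exactly 1-periodic and analytically
  differentiable in time) at a set of arclength nodes;
* the effective stroke occupies 4/13 of the cycle (matching the conventional
  13-state description, states 1-4 effective / 5-13 recovery), giving a
  higher tip speed during the effective stroke;
* during recovery a curvature wave bends the cilium backward and downward.

Because positions are obtained by integrating a unit tangent, the arclength
equals ``L`` at every phase by construction and the base is always at the
origin.

Lattice
-------
The reduced (counter-diagonal) domain carries one row of cilia along x' with
a uniform phase ramp ``phi_i = i / n``: every beat state appears exactly once
per metachronal wavelength.  With the effective stroke towards +x', a phase
that *increases* with x' makes the metachronal wave travel towards -x', i.e.
*antiplectic* coordination (wave opposes the effective stroke).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "BeatModel", "synthetic_beat_model", "beat_shape", "beat_velocity",
    "CiliaLattice", "build_lattice", "LagrangianMarkers",
    "mesh_cilium_surface", "marker_counts", "MarkerField",
]

EFFECTIVE_FRACTION = 4.0 / 13.0  # states 1-4 of the 13-state cycle


# ---------------------------------------------------------------------------
# Beat model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeatModel:
    """Truncated-Fourier cilium beat (synthetic tracheal beat pattern).

    ``theta(s_j, phi) = a0_j + sum_m a_jm cos(2 pi m phi) + b_jm sin(2 pi m phi)``

    Attributes
    ----------
    s_nodes
        Arclength fractions (0..1) at which the tangent-angle series is stored.
    a0, a, b
        Fourier coefficients; shapes ``(n_s,)``, ``(n_s, n_modes)``.
    length
        Cilium length L (m).
    frequency
        Beat frequency (Hz); the period is ``1 / frequency``.
    n_states
        Number of reference states used to describe the cycle (13).
    """

    s_nodes: np.ndarray
    a0: np.ndarray
    a: np.ndarray
    b: np.ndarray
    length: float = 5e-6
    frequency: float = 15.0
    n_states: int = 13
    effective_fraction: float = EFFECTIVE_FRACTION
    _n_quad: int = 200

    def __post_init__(self) -> None:
        n_s = len(self.s_nodes)
        if self.a0.shape != (n_s,) or self.a.shape[0] != n_s \
                or self.a.shape != self.b.shape:
            raise ValueError("ill-sized beat coefficient table")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    @property
    def n_modes(self) -> int:
        return self.a.shape[1]

    def tangent_angle(self, phase) -> np.ndarray:
        """theta at the arclength nodes; shape ``(n_phase, n_s)``."""
        ph = np.atleast_1d(np.asarray(phase, dtype=float))
        m = np.arange(1, self.n_modes + 1)
        arg = 2.0 * np.pi * ph[:, None] * m[None, :]
        return (self.a0[None, :]
                + np.cos(arg) @ self.a.T + np.sin(arg) @ self.b.T)

    def tangent_angle_rate(self, phase) -> np.ndarray:
        """d theta / d phase (per cycle) at the arclength nodes."""
        ph = np.atleast_1d(np.asarray(phase, dtype=float))
        m = np.arange(1, self.n_modes + 1)
        arg = 2.0 * np.pi * ph[:, None] * m[None, :]
        fac = 2.0 * np.pi * m
        return (-np.sin(arg) * fac) @ self.a.T + (np.cos(arg) * fac) @ self.b.T

    def _fine(self, values: np.ndarray) -> np.ndarray:
        """Interpolate node values onto the fine quadrature grid."""
        sq = np.linspace(0.0, 1.0, self._n_quad + 1)
        return np.stack([np.interp(sq, self.s_nodes, row) for row in values])

    def centerline(self, phase) -> tuple[np.ndarray, np.ndarray]:
        """Positions and tangent angles on the fine arclength grid.

        Returns ``(s_fine, xyz)`` with ``xyz`` of shape
        ``(n_phase, n_quad+1, 3)`` in metres; the beat plane is x-z.
        """
        theta = self._fine(self.tangent_angle(phase))
        sq = np.linspace(0.0, 1.0, self._n_quad + 1)
        tx, tz = np.sin(theta), np.cos(theta)
        ds = self.length / self._n_quad
        x = np.concatenate([np.zeros_like(tx[:, :1]),
                            np.cumsum(0.5 * (tx[:, 1:] + tx[:, :-1]) * ds, axis=1)],
                           axis=1)
        z = np.concatenate([np.zeros_like(tz[:, :1]),
                            np.cumsum(0.5 * (tz[:, 1:] + tz[:, :-1]) * ds, axis=1)],
                           axis=1)
        xyz = np.stack([x, np.zeros_like(x), z], axis=-1)
        return sq, xyz

    def centerline_velocity(self, phase) -> tuple[np.ndarray, np.ndarray]:
        """Material velocity of centreline points (m/s) on the fine grid."""
        theta = self._fine(self.tangent_angle(phase))
        rate = self._fine(self.tangent_angle_rate(phase)) * self.frequency
        sq = np.linspace(0.0, 1.0, self._n_quad + 1)
        vx_i = np.cos(theta) * rate
        vz_i = -np.sin(theta) * rate
        ds = self.length / self._n_quad
        vx = np.concatenate([np.zeros_like(vx_i[:, :1]),
                             np.cumsum(0.5 * (vx_i[:, 1:] + vx_i[:, :-1]) * ds,
                                       axis=1)], axis=1)
        vz = np.concatenate([np.zeros_like(vz_i[:, :1]),
                             np.cumsum(0.5 * (vz_i[:, 1:] + vz_i[:, :-1]) * ds,
                                       axis=1)], axis=1)
        return sq, np.stack([vx, np.zeros_like(vx), vz], axis=-1)

    @property
    def fourier_coefficients(self) -> np.ndarray:
        """Coefficient table, shape ``(n_s, 1 + 2 n_modes)``: [a0, a_m, b_m]."""
        return np.concatenate([self.a0[:, None], self.a, self.b], axis=1)


def _periodic_gaussian_smooth(samples: np.ndarray, sigma_cycles: float) -> np.ndarray:
    """Smooth periodic samples (axis -1) with a wrapped Gaussian kernel."""
    n = samples.shape[-1]
    k = np.fft.rfftfreq(n, d=1.0 / n)  # integer mode numbers
    damp = np.exp(-0.5 * (2.0 * np.pi * k * sigma_cycles) ** 2)
    return np.fft.irfft(np.fft.rfft(samples, axis=-1) * damp, n=n, axis=-1)


def synthetic_beat_model(length: float = 5e-6, frequency: float = 15.0,
                         n_modes: int = 12, n_s: int = 33,
                         sweep_amplitude: float = 1.13,
                         bend_amplitude: float = 1.6,
                         effective_fraction: float = EFFECTIVE_FRACTION,
                         smoothing: float = 0.02) -> BeatModel:
    """Construct the synthetic tracheal beat pattern (see module docstring).

    Parameters
    ----------
    sweep_amplitude
        Half-angle of the tip sweep (rad); the straight cilium tilts between
        ``-sweep_amplitude`` and ``+sweep_amplitude`` from vertical.
    bend_amplitude
        Peak extra tangent angle (rad) of the recovery-stroke bend at the tip.
    effective_fraction
        Fraction of the cycle spent in the effective stroke (default 4/13).
    smoothing
        Width (cycles) of the periodic Gaussian used to smooth the piecewise
        stroke definition before Fourier truncation.
    """
    n_phase = 512
    phi = np.arange(n_phase) / n_phase
    # Phase warp: first half of the base cycle (sweep forward) is compressed
    # into the effective fraction, the second half stretched over recovery.
    p = np.where(phi < effective_fraction,
                 0.5 * phi / effective_fraction,
                 0.5 + 0.5 * (phi - effective_fraction) / (1.0 - effective_fraction))
    sweep = -sweep_amplitude * np.cos(2.0 * np.pi * p)
    bend = bend_amplitude * np.minimum(np.sin(2.0 * np.pi * p), 0.0)
    s = np.linspace(0.0, 1.0, n_s)
    theta = sweep[None, :] + bend[None, :] * s[:, None] ** 2
    theta = _periodic_gaussian_smooth(theta, smoothing)
    coef = np.fft.rfft(theta, axis=-1) / n_phase
    a0 = coef[:, 0].real
    a = 2.0 * coef[:, 1:n_modes + 1].real
    b = -2.0 * coef[:, 1:n_modes + 1].imag
    return BeatModel(s_nodes=s, a0=a0, a=a, b=b, length=length,
                     frequency=frequency,
                     effective_fraction=effective_fraction)


@lru_cache(maxsize=8)
def _default_model(length: float, frequency: float) -> BeatModel:
    return synthetic_beat_model(length=length, frequency=frequency)


def beat_shape(phase, s, model: BeatModel | None = None) -> np.ndarray:
    """Centreline point(s) at beat phase ``phase`` and arclength fraction ``s``.

    ``phase`` is in cycles (any real; the beat is 1-periodic), ``s`` in [0, 1].
    Returns positions in metres relative to the cilium base, shape ``(..., 3)``.
    """
    model = model or _default_model(5e-6, 15.0)
    sq, xyz = model.centerline(np.mod(phase, 1.0))
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    out = np.stack([np.stack([np.interp(s_arr, sq, xyz[i, :, k])
                              for k in range(3)], axis=-1)
                    for i in range(xyz.shape[0])])
    return out.squeeze()


def beat_velocity(phase, s, model: BeatModel | None = None) -> np.ndarray:
    """Material velocity (m/s) of the centreline point at (phase, s).

    Computed by analytic differentiation of the Fourier series in phase
    (scaled by the beat frequency), not by finite differences.
    """
    model = model or _default_model(5e-6, 15.0)
    sq, v = model.centerline_velocity(np.mod(phase, 1.0))
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    out = np.stack([np.stack([np.interp(s_arr, sq, v[i, :, k])
                              for k in range(3)], axis=-1)
                    for i in range(v.shape[0])])
    return out.squeeze()


# ---------------------------------------------------------------------------
# Lattice
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CiliaLattice:
    """Row of cilia along x' of the reduced domain with a uniform phase ramp."""

    count: int
    spacing: float            # m, centre-to-centre along x'
    length: float = 5e-6
    diameter: float = 0.15e-6
    frequency: float = 15.0
    wavelength: float = 55e-6  # nominal metachronal wavelength (m)
    metachrony: str = "antiplectic"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("need at least one cilium")
        if self.spacing <= 0 or self.wavelength <= 0:
            raise ValueError("spacing and wavelength must be positive")
        if self.metachrony not in ("antiplectic", "symplectic"):
            raise ValueError(f"unknown metachrony {self.metachrony!r}")

    @property
    def phases(self) -> np.ndarray:
        """Phase of each cilium (fraction of a cycle, uniformly spaced).

        Antiplectic coordination: phase increases with x' so the metachronal
        wave runs towards -x', opposing the +x' effective stroke.
        """
        ramp = np.arange(self.count) / self.count
        return ramp if self.metachrony == "antiplectic" else (-ramp) % 1.0

    def base_points(self, y: float = 0.0) -> np.ndarray:
        """Base (anchor) positions on the epithelium, shape ``(count, 3)``."""
        x = (np.arange(self.count) + 0.5) * self.spacing
        out = np.zeros((self.count, 3))
        out[:, 0] = x
        out[:, 1] = y
        return out


def build_lattice(count: int = 100, spacing: float = 0.4e-6, *,
                  length: float = 5e-6, diameter: float = 0.15e-6,
                  frequency: float = 15.0, wavelength: float = 55e-6,
                  metachrony: str = "antiplectic") -> CiliaLattice:
    """Build the cilia lattice of the reduced strip.

    With the default 100 cilia the adjacent-cilium phase difference is 0.01 of
    a cycle and the strip spans one metachronal wavelength.
    """
    return CiliaLattice(count=count, spacing=spacing, length=length,
                        diameter=diameter, frequency=frequency,
                        wavelength=wavelength, metachrony=metachrony)


# ---------------------------------------------------------------------------
# Surface markers
# ---------------------------------------------------------------------------

@dataclass
class LagrangianMarkers:
    """Lagrangian surface markers of one or more cilia.

    ``X`` positions (m), ``U`` velocities (m/s), ``dV`` element volumes (m^3),
    ``C`` marker concentrations (kg/m^3), plus the (axial x angular) counts.
    """

    X: np.ndarray
    U: np.ndarray
    dV: np.ndarray
    n_ax: int
    n_ang: int
    cilium_id: np.ndarray | None = None
    C: np.ndarray | None = None
    #: Element volumes used when spreading *momentum* forcing.  Equal to
    #: ``dV`` when the cilium surface is grid-resolved; clamped from below to
    #: one grid cell per axial station (``dx^3 / n_ang`` per marker) when the
    #: cilium is thinner than a cell, the thin-fiber direct-forcing
    #: convention -- otherwise the velocity enforcement stalls.
    dV_force: np.ndarray | None = None

    def __len__(self) -> int:
        return self.X.shape[0]


def marker_counts(length: float, diameter: float, dx: float) -> tuple[int, int]:
    """Marker counts (axial, angular) so marker spacing matches the grid.

    ``n_ax = round(L / dx)`` and ``n_ang = round(pi d / dx)`` reproduce the
    published resolutions for the M1..M4 meshes (39x4, 51x5, 64x6, 77x7).
    Counts are clamped to at least (4, 3); if the resulting marker spacing
    exceeds 1.5 grid cells the delta kernel under-resolves the surface and a
    warning is raised.
    """
    n_ax = max(4, round(length / dx))
    n_ang = max(3, round(np.pi * diameter / dx))
    if round(length / dx) < 4 or round(np.pi * diameter / dx) < 3:
        warnings.warn(
            "grid spacing exceeds the cilium surface scale (marker spacing "
            "> 1.5 cells before clamping); IBM kernel under-resolves the "
            "cilium", stacklevel=2)
    return n_ax, n_ang


def mesh_cilium_surface(centerline: np.ndarray, tangent_angle: np.ndarray,
                        diameter: float, n_ax: int, n_ang: int, dx: float,
                        length: float,
                        centerline_velocity: np.ndarray | None = None,
                        angle_rate: np.ndarray | None = None,
                        ) -> LagrangianMarkers:
    """Tile the lateral surface of a bent cylinder with one shell of markers.

    Parameters
    ----------
    centerline, tangent_angle
        Axial station positions ``(n_ax, 3)`` (at arclength midpoints) and the
        planar tangent angles there (rad from the z axis, beat plane x-z).
    diameter
        Cilium diameter (m).
    dx
        Fluid grid spacing; element volumes are (patch area) x dx, the
        one-cell-thick shell convention of the direct-forcing scheme, so
        ``sum dV = pi * diameter * length * dx``.
    centerline_velocity, angle_rate
        Optional station velocities ``(n_ax, 3)`` and d(theta)/dt (rad/s) used
        to assign marker velocities (including the spin of the cross-section).
    """
    if n_ax < 1 or n_ang < 1:
        raise ValueError("marker counts must be positive")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    r = diameter / 2.0
    alpha = 2.0 * np.pi * np.arange(n_ang) / n_ang
    ct, st = np.cos(tangent_angle), np.sin(tangent_angle)
    # Normal frame of the planar centreline: e1 in-plane, e2 out-of-plane.
    e1 = np.stack([ct, np.zeros_like(ct), -st], axis=-1)   # (n_ax, 3)
    e2 = np.broadcast_to(np.array([0.0, 1.0, 0.0]), e1.shape)
    offset = (r * np.cos(alpha)[None, :, None] * e1[:, None, :]
              + r * np.sin(alpha)[None, :, None] * e2[:, None, :])
    X = (centerline[:, None, :] + offset).reshape(-1, 3)
    if centerline_velocity is not None:
        de1 = np.stack([-st, np.zeros_like(st), -ct], axis=-1) \
            * (angle_rate if angle_rate is not None else 0.0)[:, None]
        U = (centerline_velocity[:, None, :]
             + r * np.cos(alpha)[None, :, None] * de1[:, None, :]).reshape(-1, 3)
    else:
        U = np.zeros_like(X)
    patch = (length / n_ax) * (np.pi * diameter / n_ang)
    dV = np.full(X.shape[0], patch * dx)
    dV_force = np.maximum(dV, dx**3 / n_ang)
    return LagrangianMarkers(X=X, U=U, dV=dV, n_ax=n_ax, n_ang=n_ang,
                             dV_force=dV_force)


class MarkerField:
    """Time-resolved marker set of a whole lattice, with phase tabulation.

    Building the surface shell from the Fourier beat at every substep is
    needlessly expensive, so the single-cilium shell (positions and
    velocities relative to the base) is tabulated over ``n_table`` phases and
    linearly interpolated in phase at run time.  The table resolution keeps
    the interpolation error far below the delta-kernel width.
    """

    def __init__(self, lattice: CiliaLattice, dx: float,
                 model: BeatModel | None = None, n_table: int = 128,
                 y_center: float = 0.0):
        self.lattice = lattice
        self.model = model or synthetic_beat_model(
            length=lattice.length, frequency=lattice.frequency)
        self.n_ax, self.n_ang = marker_counts(lattice.length,
                                              lattice.diameter, dx)
        self.n_table = n_table
        self._base = lattice.base_points(y=y_center)
        s_mid = (np.arange(self.n_ax) + 0.5) / self.n_ax
        phases = np.arange(n_table) / n_table
        sq, xyz = self.model.centerline(phases)
        _, vel = self.model.centerline_velocity(phases)
        theta = self.model._fine(self.model.tangent_angle(phases))
        rate = self.model._fine(self.model.tangent_angle_rate(phases)) \
            * self.model.frequency
        nm = self.n_ax * self.n_ang
        self._Xtab = np.empty((n_table, nm, 3))
        self._Utab = np.empty((n_table, nm, 3))
        for i in range(n_table):
            P = np.stack([np.interp(s_mid, sq, xyz[i, :, k]) for k in range(3)],
                         axis=-1)
            V = np.stack([np.interp(s_mid, sq, vel[i, :, k]) for k in range(3)],
                         axis=-1)
            th = np.interp(s_mid, sq, theta[i])
            dth = np.interp(s_mid, sq, rate[i])
            mk = mesh_cilium_surface(P, th, lattice.diameter, self.n_ax,
                                     self.n_ang, dx, lattice.length,
                                     centerline_velocity=V, angle_rate=dth)
            self._Xtab[i] = mk.X
            self._Utab[i] = mk.U
            self._dV = mk.dV
            self._dV_force = mk.dV_force
        self.n_markers = nm * lattice.count

    def markers_at(self, t: float) -> LagrangianMarkers:
        """Markers of every cilium at time ``t`` (phases advance at f Hz)."""
        lat = self.lattice
        ph = np.mod(lat.phases + t * lat.frequency, 1.0) * self.n_table
        i0 = np.floor(ph).astype(int) % self.n_table
        i1 = (i0 + 1) % self.n_table
        wgt = (ph - np.floor(ph))[:, None, None]
        X = (1.0 - wgt) * self._Xtab[i0] + wgt * self._Xtab[i1]
        U = (1.0 - wgt) * self._Utab[i0] + wgt * self._Utab[i1]
        X = X + self._base[:, None, :]
        nm = self.n_ax * self.n_ang
        cid = np.repeat(np.arange(lat.count), nm)
        return LagrangianMarkers(
            X=X.reshape(-1, 3), U=U.reshape(-1, 3),
            dV=np.tile(self._dV, lat.count), n_ax=self.n_ax,
            n_ang=self.n_ang, cilium_id=cid,
            dV_force=np.tile(self._dV_force, lat.count))
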