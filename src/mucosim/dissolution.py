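"""Noyes-Whitney dissolution of a single spherical drug particle.

A drug particle deposited on the air-mucus interface dissolves following the
Noyes-Whitney mass-transfer law

    dm/dt = A * D_ASL * (C_s - C_b) / h,

with ``A = 4 pi r^2`` the particle surface, ``h`` the diffusion-layer
thickness (approximated by the dynamic radius ``r`` for particles below 30 um)
and ``C_b`` the bulk concentration of already-dissolved drug.  The rate then
simplifies to ``dm/dt = 4 pi r D_ASL (C_s - C_b)`` and the equivalent-radius
ODE is ``dr/dt = -D_ASL (C_s - C_b) / (rho r)``.

For constant ``C_b`` the ODE has the exact solution

    r(t)^2 = r0^2 - 2 D_ASL (C_s - C_b) t / rho,

so ``advance_particle`` integrates each step in closed form with the step's
(frozen) bulk concentration -- stiff-safe through the square-root singularity
and landing exactly on r = 0.  With ``C_b = 0`` the complete-dissolution time
is ``t_d = rho r0^2 / (2 D_ASL C_s)`` and the dissolved fraction is
``1 - (1 - t/t_d)^{3/2}``.

The dissolved mass is distributed uniformly across the upper surface of the
ASL as a Neumann flux ``m''_d = (dm_dissolved/dt) / A_top``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["DrugSpec", "DRUGS", "ParticleState", "dissolution_rate",
           "advance_particle", "surface_flux", "complete_dissolution_time",
           "dissolved_fraction", "dissolve_history"]


@dataclass(frozen=True)
class DrugSpec:
    """Pharmacokinetic drug properties.

    ``solubility`` (C_s) and ``density`` are stored in SI (kg/m^3);
    ``diffusivity`` (D_ASL, m^2/s) is taken equal to the aqueous diffusion
    coefficient of the dissolved molecule and doubles as the mucus
    diffusivity D_M.
    """

    name: str
    molar_mass: float      # g/mol
    density: float         # kg/m^3
    solubility: float      # kg/m^3
    diffusivity: float     # m^2/s

    def __post_init__(self) -> None:
        for f in ("molar_mass", "density", "solubility", "diffusivity"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


#: Default drug set: Rifampicin, Tiotropium bromide, Salbutamol sulfate.
#: (mg/ml == kg/m^3; g/cm^3 == 1000 kg/m^3; cm^2/s == 1e-4 m^2/s)
DRUGS = {
    "RIF": DrugSpec("RIF", molar_mass=822.9, density=1320.0,
                    solubility=1.71, diffusivity=4.10e-10),
    "TIO": DrugSpec("TIO", molar_mass=472.4, density=1500.0,
                    solubility=37.0, diffusivity=5.15e-10),
    "SAL": DrugSpec("SAL", molar_mass=576.7, density=1300.0,
                    solubility=263.0, diffusivity=4.60e-10),
}


@dataclass(frozen=True)
class ParticleState:
    """State of one dissolving spherical particle."""

    radius: float                  # m
    drug: DrugSpec
    dissolved_mass: float = 0.0    # kg, cumulative
    t: float = 0.0                 # s

    @property
    def mass(self) -> float:
        return self.drug.density * (4.0 / 3.0) * np.pi * self.radius**3

    @property
    def area(self) -> float:
        return 4.0 * np.pi * self.radius**2

    @property
    def diffusion_layer(self) -> float:
        """h = dynamic radius (valid below 30 um)."""
        return self.radius

    @classmethod
    def from_diameter(cls, diameter: float, drug: DrugSpec) -> "ParticleState":
        return cls(radius=diameter / 2.0, drug=drug)


def dissolution_rate(particle: ParticleState, c_bulk: float = 0.0) -> float:
    """Particle mass rate dm/dt (kg/s; negative while dissolving).

    ``A D (C_s - C_b) / h`` with ``A = 4 pi r^2`` and ``h = r`` reduces to
    ``4 pi r D (C_s - C_b)``; zero once fully dissolved.
    """
    if particle.radius <= 0.0:
        return 0.0
    drug = particle.drug
    if c_bulk > drug.solubility:
        warnings.warn("bulk concentration exceeds solubility; "
                      "re-precipitation is outside the model", stacklevel=2)
    return -4.0 * np.pi * particle.radius * drug.diffusivity \
        * (drug.solubility - c_bulk)


def advance_particle(particle: ParticleState, c_bulk: float,
                     dt: float) -> ParticleState:
    """Advance the particle by ``dt`` with the bulk concentration frozen.

    Uses the exact constant-``C_b`` solution of the radius ODE, clamping at
    r = 0 (the square root lands on zero exactly at the dissolution time
    within the step), and updates the dissolved-mass ledger.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if particle.radius <= 0.0:
        return replace(particle, t=particle.t + dt)
    drug = particle.drug
    r2 = particle.radius**2 - 2.0 * drug.diffusivity \
        * (drug.solubility - c_bulk) * dt / drug.density
    r_new = np.sqrt(max(r2, 0.0))
    dm = drug.density * (4.0 / 3.0) * np.pi \
        * (particle.radius**3 - r_new**3)
    return replace(particle, radius=r_new,
                   dissolved_mass=particle.dissolved_mass + dm,
                   t=particle.t + dt)


def surface_flux(dissolved_rate: float, top_area: float) -> float:
    """Uniform top-boundary mass flux m''_d (kg/m^2/s) from a dissolution rate.

    The dissolved mass is distributed uniformly over the air-mucus interface:
    ``m''_d = (rate of mass release) / A_top``.
    """
    if top_area <= 0:
        raise ValueError("top_area must be positive")
    return dissolved_rate / top_area


def complete_dissolution_time(drug: DrugSpec, diameter: float = 5e-6,
                              c_bulk: float = 0.0) -> float:
    """Closed-form dissolution time at constant bulk concentration.

    ``t_d = rho r0^2 / (2 D (C_s - C_b))``.
    """
    r0 = diameter / 2.0
    return drug.density * r0**2 \
        / (2.0 * drug.diffusivity * (drug.solubility - c_bulk))


def dissolved_fraction(drug: DrugSpec, t, diameter: float = 5e-6) -> np.ndarray:
    """Closed-form dissolved mass fraction at ``C_b = 0``:
    ``1 - (1 - t/t_d)^{3/2}`` (clamped at 1)."""
    td = complete_dissolution_time(drug, diameter)
    x = np.clip(1.0 - np.asarray(t, dtype=float) / td, 0.0, None)
    return 1.0 - x**1.5


def dissolve_history(drug: DrugSpec, diameter: float = 5e-6,
                     c_bulk: float = 0.0, n_steps: int = 20000):
    """Integrate the particle ODE at fixed ``C_b``; returns a record dict.

    The record holds arrays ``t``, ``radius``, ``dissolved_fraction`` and the
    scalar ``t_d`` (time at which the radius reaches zero, resolved exactly
    within the final step).
    """
    p = ParticleState.from_diameter(diameter, drug)
    m0 = p.mass
    t_cap = 1.2 * complete_dissolution_time(drug, diameter,
                                            min(c_bulk, 0.5 * drug.solubility))
    dt = t_cap / n_steps
    ts, rs, fr = [0.0], [p.radius], [0.0]
    t_d = np.nan
    while p.radius > 0.0:
        r_before = p.radius
        p = advance_particle(p, c_bulk, dt)
        if p.radius == 0.0 and np.isnan(t_d):
            # exact hit time inside the step
            dtd = drug.density * r_before**2 \
                / (2.0 * drug.diffusivity * (drug.solubility - c_bulk))
            t_d = (p.t - dt) + dtd
        ts.append(p.t)
        rs.append(p.radius)
        fr.append(p.dissolved_mass / m0)
    return {"t": np.array(ts), "radius": np.array(rs),
            "dissolved_fraction": np.array(fr), "t_d": float(t_d),
            "initial_mass": m0}
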