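# Methods

## Physical model and assumptions

The simulator models a planar segment of tracheal airway surface liquid
(ASL): the ratio of ASL depth (~17 µm) to airway radius is O(10⁻²), so
curvature is neglected.  The film has two immiscible layers with flat
interfaces — a Newtonian periciliary liquid (PCL, default depth 7 µm,
viscosity 1 mPa s) and a viscoelastic mucus layer (default depth 10 µm) —
sharing density 1000 kg/m³.  Membrane tension at the PCL–mucus and
air–mucus interfaces is neglected, as is gravity and any airflow above the
film.

Coupling is one-way throughout: cilia drive the fluid but are not bent back
by it (the beat is kinematically prescribed); the flow transports the
dissolved drug but the drug does not alter the flow or the rheology.

### Reduced periodic domain

A full carpet of n × n cilia with a one-phase difference in both lattice
directions repeats itself along one diagonal.  The computational domain is
therefore a narrow periodic strip along the counter-diagonal containing
every beat phase exactly once (n cilia in a row, phase ramp i/n); the full
carpet is a tiling of this strip.  The strip length is grid-quantized, so
the cilium spacing is derived as L_x′/n rather than taken from the nominal
0.4 µm table value (at the reference mesh this gives 0.388 µm); the nominal
spacing and the 55 µm metachronal wavelength remain independent,
documentation-level config values because the two are mutually inconsistent
on any fixed strip.

### Cilium beat (synthetic)

The classic description of the rabbit-trachea beat is a truncated Fourier
series fitted to observed centreline shapes.  That coefficient table is not
redistributable here, so `mucosim.cilia` generates a **synthetic** beat with
the same mathematical structure and the properties that drive mucociliary
transport:

* the centreline is an inextensible planar curve of length L anchored at
  the origin, defined through a tangent angle θ(s, φ);
* θ is built from a smooth two-stroke script — an effective stroke
  occupying 4/13 of the cycle in which the straight cilium sweeps from
  −65° to +65° from vertical, and a recovery stroke in which a tangent-angle
  bend of up to 1.6 rad (weighted s², i.e. concentrated at the tip) carries
  the cilium back low over the epithelium — smoothed by a periodic Gaussian
  (σ = 0.02 cycles) and truncated to 12 Fourier modes in phase;
* positions integrate a unit tangent, so the arclength equals L *exactly*
  at every phase, and velocities differentiate the Fourier series
  analytically (a finite-difference oracle cross-checks them in the tests).

Measured properties of the default beat: mean tip speed 545 µm/s during the
effective stroke versus 250 µm/s during recovery; cycle-averaged velocity
exactly zero; centreline always inside 0 ≤ z ≤ L.  The stroke amplitudes
were chosen once as representative of tracheal cilia and are not calibrated
against any published table.

### Surface markers

Each cilium carries one shell of Lagrangian markers at arclength midpoints:
n_ax = round(L/Δx) axial stations × n_ang = round(πd/Δx) angular positions,
which reproduces the published per-mesh marker counts (39×4 … 77×7) across
the four bundled grid presets.  Element volumes follow the one-cell-thick
shell convention ΔV = (patch area)·Δx, so ΣΔV = πdLΔx.  When the grid is
coarser than the cilium surface (counts clamp at 4×3) a warning is raised;
for *momentum forcing only*, element volumes are then clamped from below to
one grid cell per axial station (Δx³/n_ang per marker), the thin-fiber
direct-forcing convention — without it the velocity enforcement stalls at
coarse resolution.  Marker positions/velocities are tabulated over 128
phases and linearly interpolated at run time.

## Flow solver

Staggered (MAC) uniform grid, periodic in x′/y′; free slip, u_z = 0,
∂p/∂z = 0, τ = 0 at the air–mucus interface; no slip and ∂p/∂z = 0 at the
epithelium (an oscillating wall velocity can be prescribed for benchmarks).
One time step:

1. **Giesekus update** (explicit Euler): per-mode symmetric stresses at
   cell centres, upper-convected terms from the centred velocity gradient,
   central-difference advection with zero ghosts (the stress vanishes at
   both z boundaries), hard-masked to the mucus layer.  Modes: (λ, η, α) =
   (0.0089, 0.0298, 0.2), (0.0821, 0.062, 0.3), (0.466, 0.2493, 0.5),
   (3.129, 1.4215, 0.5), (49.73, 2.2034, 0.5).
2. **Momentum predictor**: explicit conservative advection and stress
   divergence; *implicit* (backward-Euler) solvent diffusion solved per
   component as a Helmholtz problem — FFT in x′/y′, vectorized Thomas solve
   in z.  The implicit treatment is essential: ν_sΔt/Δx² is O(10³) at
   physiological resolution, far beyond any explicit limit.
3. **Direct forcing**: interpolate the predictor at the markers, spread the
   velocity deficit (U_l − u*)/Δt back as a body force; repeated
   (multidirect) `n_force_iter` times (default 2; coarse under-resolved
   runs use 4–6 since the kernel self-overlap per iteration is only
   ~ΔV/(8Δx³)).
4. **Projection**: FFT/tridiagonal Poisson solve with Neumann walls (the
   singular lateral zero mode is deflated and mean-grounded), making the
   discrete divergence vanish to round-off — the 10⁻⁸·(U/Δx) acceptance
   bound holds with orders of magnitude to spare.

Default Δt = T_c/2000 with an advective-CFL abort (|u|maxΔt/Δx < 0.8).  The
explicit Giesekus update is stable because Δt·|∇u| stays well below one.

Time-periodic episodes are recorded as a `CycleReplay` (one beat cycle of
velocity snapshots, linearly interpolated in time and replayed
periodically), which one-way coupling makes exact up to interpolation
error.  Spin-up before recording defaults to 2–3 beat cycles: the Newtonian
flow settles within a cycle (tested to 1% periodicity); the slowest
Giesekus mode (λ = 49.7 s) never fully equilibrates on simulated
time-scales — its modulus is small (0.044 Pa) and the residual drift is
accepted and documented rather than hidden behind an unattainable spin-up.
Because the initial state is quiescent, "t = 0" metrics are reported after
spin-up at phase 0; exact published layer-velocity values are not claimed.

## Dissolution

Noyes–Whitney with A = 4πr² and diffusion-layer thickness h = r (valid for
r < 30 µm) reduces to the radius ODE dr/dt = −D(C_s − C_b)/(ρr).  Each step
freezes C_b and advances in closed form r² → r² − 2D(C_s − C_b)Δt/ρ, which
is stiff-safe through the square-root singularity and lands exactly on
r = 0 (the within-step hit time is resolved analytically).  Dissolved mass
enters the domain as a uniform Neumann flux m″_d = ṁ/A_top at the
air–mucus interface; the wall-normal direction is z.  C_b defaults to the
domain-averaged concentration (a top-layer average is available as
`c_bulk_mode="top_layer"`).  The particle feeds the full-lattice interface
area (100 × 0.4 µm per side) even when the transport grid is a reduced
column or strip — ledgers are rescaled by the area ratio, keeping
concentrations physical; omitting this inflates C_b and distorts the
dissolution time of low-solubility drugs by tens of percent.

## Transport

Three-substep explicit Runge–Kutta (γ = 8/15, 5/12, 3/4;
ζ = 0, −17/60, −5/12; stage times 8/15, 2/3, 1) with second-order central
differences in conservative flux form.  Boundary handling: antisymmetric
ghost for the perfect-sink base (c = 0 on the wall), flux-carrying ghost at
the top (the top z-face diffusive flux *is* m″_d), wall z-faces carry no
advective flux.  Ledgers (injected, deposited, attached) accumulate the
same discrete fluxes with the same RK weights as the field update, so the
global budget injected = in-domain + deposited + attached closes to
round-off; the solver aborts if drift exceeds 10⁻⁸ of the particle mass per
step.  Central differences can undershoot; min(c) is monitored and reported,
never clipped (clipping would break the budget).

The stable step is 0.5·2.51Δx²/(12D) against diffusion and
0.5·√3·Δx/(3|u|) against advection (RK3 real/imaginary stability
intervals).

### Ciliary attachment

After each substep the provisional field is interpolated to the markers
(C_l*), the target C_l = (1 − κ_att)C_l* is set, and the deficit is spread
back as a mass source; interpolate/spread corrections repeat N_i = 4 times
(the published iteration count), with the accumulated source applied from
the substep base field.  κ_att = 0 is exact identity; κ_att = 1 enforces
the maximum-attachment limit C_l = 0.  For the Roma kernel Σφ² = 1/2 per
axis, so a single resolved marker contracts its interpolated value by the
factor (1 − 1/8) per pass — enforcement is asymptotic, not exact, and the
tests assert this computed geometric rate.

The ciliary attachment ratio is an *output*: CAR = attached mass /
cumulative availability, where availability sums Σ_l C_l*ΔV_l over
substeps.  This makes the reported CAR resolution-dependent (it counts
exposure per substep); the underlying rate law behind the published CAR
values is not specified, so the per-substep absorption fraction κ_att is
the package's control knob and a bisection helper can calibrate it to a
CAR target.

### A structural consequence of linear attachment

The attachment law is linear in concentration.  With a time-periodic flow,
superposition then makes the fate of injected drug independent of the
injection schedule — and therefore of solubility, which only sets that
schedule.  Diffusivity dependence also cancels when the time step tracks
the diffusive stability limit (removal per substep × substeps per transit
is D-independent).  Measured consequence: at fixed κ_att = 0.02 the
reduced-scale deposition fractions of RIF/TIO/SAL agree to three digits
(0.642).  The published solubility ordering of deposition (RIF > TIO > SAL)
therefore cannot emerge from any concentration-linear attachment mechanism;
reproducing it would require a nonlinear (e.g. cooperative) adsorption law
for which no data exists.  The corresponding trend test is retained
faithfully and fails; no mechanism was invented to force it.

What *is* reproduced: attachment strictly reduces epithelial deposition
(monotone in κ_att, e.g. 99.9% → 64% → 29% across κ_att = 0/0.02/0.08 for
TIO), all mass ledgers close, and deposition-rate peak times are far
shorter than complete-deposition times, matching the published structure.

## Verification

* 1-D convection–diffusion benchmark (κ = 0.8, β = 0.1, advecting
  spreading Gaussian with time-dependent Dirichlet data): the production
  RK3/central kernel reaches max relative error 1.0×10⁻⁶ at 128 cells
  (doubling from 64 until the 3.5×10⁻⁶ bound is met; the reference did not
  state its resolution) with convergence slope 2.00.
* Stokes oscillating-wall flow: 96-cell column, benchmark fluid ν = 1,
  ω = 24π, initialised from the exact profile, matches the classical
  solution within 2% (measured 0.2%).
* Giesekus steady shear: α = 0 against the closed-form upper-convected
  Maxwell solution (exact to time-marching tolerance); α > 0 against an
  independent `fsolve` root of the algebraic steady-state system (≤0.1%).
* Kernel identities: partition of unity, exact spread conservation
  (including wall-folded stencils), self-overlap factor exactly 1/8.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own desk-scale defaults: dissolution ODEs at
2×10⁴ steps; the coupled rifampicin column at 1×1×48 cells
(~2.3×10⁵ steps); the trend study on a 24×4×12 strip with 16 cilia
(Δx = 1.42 µm, beat cycle at 900 steps, episodes at the diffusive-stability
step ≈ 4×10⁻⁴ s).  The reference meshes M1–M4 (up to 600×12×262 with 100
cilia and 77×7 markers each) are available through the same interfaces but
need cluster-scale runs; published full-resolution numbers (mean mucus
velocity 115.4 µm/s, absolute deposition percentages) are consequently
checked only qualitatively at reduced scale (positive clearance-direction
transport, periodicity, divergence-free flow).

## Known limitations

* The beat pattern is synthetic: quantitatively correct transport
  velocities (µm/s-scale layer averages) should not be expected to match
  published values even at full resolution.
* Coarse grids under-resolve the 0.15 µm cilium; forcing then relies on the
  thin-fiber volume clamp and more multidirect iterations, and the carpet
  pumps more weakly than a resolved one.
* The attachment mechanism is a per-substep linear absorption; see above
  for what this implies and excludes.
* One-way coupling excludes cilia–fluid feedback, drug-induced rheology
  changes and interface deformation by construction.
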