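"""Flow solver: quiescence, the oscillating-wall Stokes benchmark,
incompressibility, boundary conditions, Newtonian limit, propulsion."""

import numpy as np
import pytest

from mucosim.cilia import MarkerField, build_lattice
from mucosim.flow import FlowSolver, FluidProps, layer_average_velocity
from mucosim.grid import GridSpec, divergence
from mucosim.rheology import GiesekusParams


class TestQuiescence:
    def test_no_cilia_no_stress_stays_at_rest(self):
        g = GridSpec(8, 4, 12)
        solver = FlowSolver(g, dt=1e-4)
        st = solver.initial_state()
        for _ in range(25):
            st = solver.step(st)
        assert not st.u.any() and not st.v.any() and not st.w.any()

    def test_quiescent_with_stress_module_enabled(self):
        g = GridSpec(8, 4, 12)
        solver = FlowSolver(g, giesekus=GiesekusParams.hbe_mucus(), dt=1e-4)
        st = solver.initial_state()
        for _ in range(10):
            st = solver.step(st)
        assert np.abs(st.u).max() < 1e-20
        assert np.abs(st.tau).max() < 1e-20


class TestStokesSecondProblem:
    def test_oscillating_wall_profile(self):
        """Velocity above an oscillating no-slip wall matches the classical
        solution u = U exp(-z/delta) cos(omega t - z/delta) within 2%."""
        nz = 96
        g = GridSpec(1, 1, nz, lz=1.0, z_interface=0.4)
        omega, U0 = 24 * np.pi, 1.0
        delta = np.sqrt(2.0 / omega)  # nu = 1
        fluid = FluidProps(density=1.0, viscosity=1.0)
        solver = FlowSolver(g, fluid, dt=5e-5,
                            bottom_wall_velocity=lambda t:
                            (U0 * np.cos(omega * t), 0.0))
        st = solver.initial_state()
        z = g.zc()
        st.u[0, 0, :] = U0 * np.exp(-z / delta) * np.cos(-z / delta)
        for _ in range(int(1.5 * (2 * np.pi / omega) / solver.dt)):
            st = solver.step(st)
        exact = U0 * np.exp(-z / delta) * np.cos(omega * st.t - z / delta)
        assert np.abs(st.u[0, 0, :] - exact).max() / U0 < 0.02


@pytest.fixture(scope="module")
def driven_flow():
    """A few steps of a small cilia-driven viscoelastic flow."""
    g = GridSpec(16, 4, 12)
    lat = build_lattice(count=4, spacing=g.lx / 4)
    with pytest.warns(UserWarning):
        mf = MarkerField(lat, g.dx, y_center=g.ly / 2)
    solver = FlowSolver(g, giesekus=GiesekusParams.hbe_mucus(), markers=mf,
                        dt=(1 / 15) / 1000, n_force_iter=3)
    st = solver.initial_state()
    for _ in range(40):
        st = solver.step(st)
    return g, solver, st


class TestProjectionAndBCs:
    def test_divergence_free_after_projection(self, driven_flow):
        g, solver, st = driven_flow
        umax = max(np.abs(st.u).max(), np.abs(st.w).max())
        div = np.abs(divergence(st.u, st.v, st.w, g)).max()
        assert div <= 1e-8 * umax / g.dx

    def test_wall_normal_velocity_vanishes(self, driven_flow):
        _, _, st = driven_flow
        assert not st.w[:, :, 0].any()
        assert not st.w[:, :, -1].any()

    def test_stress_confined_to_mucus(self, driven_flow):
        g, _, st = driven_flow
        pcl = g.zc() < g.z_interface
        assert not st.tau[..., pcl].any()

    def test_forcing_pulls_fluid_towards_marker_velocity(self, driven_flow):
        """Direct forcing must reduce the marker-velocity mismatch well
        below the beat velocity scale."""
        _, solver, _ = driven_flow
        u_beat = np.abs(solver.markers._Utab).max()
        assert solver._last_forcing_residual < u_beat

    def test_cfl_violation_aborts(self):
        g = GridSpec(8, 4, 8)
        solver = FlowSolver(g, dt=1.0)
        st = solver.initial_state()
        st.u[:] = 1.0
        with pytest.raises(RuntimeError, match="CFL"):
            solver.step(st)


class TestNewtonianLimit:
    def test_vanishing_elastic_viscosity_matches_disabled_stress(self):
        """eta_p -> 0 reproduces the two-layer Newtonian solution obtained
        with the stress module disabled."""
        g = GridSpec(12, 4, 10)
        lat = build_lattice(count=2, spacing=g.lx / 2)
        with pytest.warns(UserWarning):
            mf = MarkerField(lat, g.dx, y_center=g.ly / 2)
        tiny = GiesekusParams((0.466,), (1e-25,), (0.5,))
        states = []
        for gies in (None, tiny):
            solver = FlowSolver(g, giesekus=gies, markers=mf,
                                dt=(1 / 15) / 1000)
            st = solver.initial_state()
            for _ in range(30):
                st = solver.step(st)
            states.append(st)
        scale = np.abs(states[0].u).max()
        assert np.abs(states[0].u - states[1].u).max() < 1e-10 * scale


class TestPropulsion:
    def test_single_cilium_drives_mucus_forward(self):
        """Cycle-averaged x'-velocity in the mucus layer is positive: the
        effective stroke pumps towards the clearance direction."""
        g = GridSpec(24, 4, 12)
        lat = build_lattice(count=1, spacing=g.lx)
        with pytest.warns(UserWarning):
            mf = MarkerField(lat, g.dx, y_center=g.ly / 2)
        solver = FlowSolver(g, giesekus=GiesekusParams.hbe_mucus(),
                            markers=mf, dt=(1 / 15) / 600, n_force_iter=4)
        st = solver.initial_state()
        for _ in range(600):  # one spin-up cycle
            st = solver.step(st)
        acc = 0.0
        for _ in range(600):
            st = solver.step(st)
            acc += layer_average_velocity(st.u, g, "mucus")
        assert acc / 600 > 0.0

    def test_beat_cycle_periodicity_newtonian(self):
        """After spin-up the layer-averaged velocity is T_c-periodic within
        1% (Newtonian two-layer flow settles within a cycle)."""
        g = GridSpec(16, 4, 10)
        lat = build_lattice(count=4, spacing=g.lx / 4)
        with pytest.warns(UserWarning):
            mf = MarkerField(lat, g.dx, y_center=g.ly / 2)
        solver = FlowSolver(g, markers=mf, dt=(1 / 15) / 500, n_force_iter=4)
        st = solver.initial_state()
        means = []
        for cycle in range(3):
            acc = 0.0
            for _ in range(500):
                st = solver.step(st)
                acc += layer_average_velocity(st.u, g, "ASL")
            means.append(acc / 500)
        assert means[2] == pytest.approx(means[1], rel=0.01)


class TestLayerAverages:
    def test_zero_velocity_averages_to_zero(self):
        g = GridSpec(8, 4, 12)
        assert layer_average_velocity(np.zeros(g.shape), g, "mucus") == 0.0

    def test_layer_partition(self):
        g = GridSpec(4, 4, 17)  # dx = 1 um: PCL 7 cells, mucus 10 cells
        u = np.zeros(g.shape)
        u[:, :, :7] = 1.0   # PCL
        u[:, :, 7:] = 3.0   # mucus
        assert layer_average_velocity(u, g, "PCL") == pytest.approx(1.0)
        assert layer_average_velocity(u, g, "mucus") == pytest.approx(3.0)
        assert layer_average_velocity(u, g, "ASL") == pytest.approx(
            (7 * 1.0 + 10 * 3.0) / 17)

    def test_unknown_layer_rejected(self):
        g = GridSpec(4, 4, 8)
        with pytest.raises(ValueError):
            layer_average_velocity(np.zeros(g.shape), g, "air")
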