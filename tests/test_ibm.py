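"""Regularized-delta kernel: partition of unity, conservation, adjointness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucosim.grid import GridSpec
from mucosim.ibm import (interpolate_scalar, interpolate_velocity, phi,
                         spread_force, spread_scalar)


@pytest.fixture
def grid():
    return GridSpec(16, 12, 20, lz=20e-6, z_interface=7e-6)


class TestKernel:
    def test_special_values(self):
        assert phi(0.0) == pytest.approx(2.0 / 3.0, abs=1e-15)
        assert phi(1.5) == pytest.approx(0.0, abs=1e-15)
        assert phi(2.0) == 0.0

    def test_nonnegative_and_continuous_at_branch_point(self):
        r = np.linspace(-2, 2, 2001)
        w = phi(r)
        assert np.all(w >= 0)
        assert abs(phi(0.5 - 1e-9) - phi(0.5 + 1e-9)) < 1e-6

    @given(st.floats(min_value=-10, max_value=10,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_partition_of_unity(self, r):
        i = np.arange(-12, 13)
        assert np.sum(phi(r - i)) == pytest.approx(1.0, abs=1e-12)

    def test_squared_sum_is_half(self):
        """The 3-point kernel's discrete self-overlap: sum phi^2 = 1/2."""
        i = np.arange(-3, 4)
        for r in (0.0, 0.21, 0.5, 0.77):
            assert np.sum(phi(r - i) ** 2) == pytest.approx(0.5, abs=1e-12)


class TestInterpolate:
    def test_constant_field(self, grid):
        c = np.full(grid.shape, 3.7)
        rng = np.random.default_rng(0)
        pts = rng.uniform([0, 0, 2 * grid.dx],
                          [grid.lx, grid.ly, grid.lz - 2 * grid.dx], (50, 3))
        assert np.allclose(interpolate_scalar(c, pts, grid), 3.7)

    def test_linear_field_first_moment(self, grid):
        """The kernel reproduces linear fields to O(dx^2) away from walls."""
        xc = (np.arange(grid.nx) + 0.5) * grid.dx
        c = np.broadcast_to(xc[:, None, None], grid.shape).copy()
        pts = np.array([[0.31 * grid.lx, 0.5 * grid.ly, 0.5 * grid.lz],
                        [0.62 * grid.lx, 0.25 * grid.ly, 0.4 * grid.lz]])
        vals = interpolate_scalar(c, pts, grid)
        assert np.allclose(vals, pts[:, 0], atol=1e-3 * grid.dx)

    def test_periodic_wrap(self, grid):
        c = np.zeros(grid.shape)
        c[0, :, :] = 1.0
        near_seam = np.array([[grid.lx - 0.2 * grid.dx, 0.5 * grid.ly,
                               0.5 * grid.lz]])
        assert interpolate_scalar(c, near_seam, grid)[0] > 0.1


class TestSpread:
    def test_exact_conservation_single_marker(self, grid):
        pts = np.array([[0.4 * grid.lx, 0.6 * grid.ly, 0.5 * grid.lz]])
        q = spread_scalar(np.array([1.0]), np.array([grid.cell_volume]),
                          pts, grid)
        assert q.sum() * grid.cell_volume == pytest.approx(grid.cell_volume,
                                                           rel=1e-14)

    def test_exact_conservation_random_cloud(self, grid):
        rng = np.random.default_rng(42)
        pts = rng.uniform([0, 0, 2 * grid.dx],
                          [grid.lx, grid.ly, grid.lz - 2 * grid.dx], (200, 3))
        Q = rng.normal(size=200)
        dV = rng.uniform(0.1, 1.0, 200) * grid.cell_volume
        q = spread_scalar(Q, dV, pts, grid)
        assert q.sum() * grid.cell_volume == pytest.approx((Q * dV).sum(),
                                                           rel=1e-12)

    def test_conservation_with_wall_folding(self, grid):
        """Markers hugging the epithelium still conserve their source."""
        pts = np.array([[0.5 * grid.lx, 0.5 * grid.ly, 0.2 * grid.dx]])
        q = spread_scalar(np.array([2.0]), np.array([grid.cell_volume]),
                          pts, grid)
        assert q.sum() * grid.cell_volume == pytest.approx(
            2.0 * grid.cell_volume, rel=1e-13)

    def test_zero_sources_zero_field(self, grid):
        pts = np.array([[1e-6, 1e-6, 8e-6]])
        q = spread_scalar(np.array([0.0]), np.array([1.0]), pts, grid)
        assert not q.any()

    def test_self_overlap_factor(self, grid):
        """interp(spread(Q)) of one marker with dV = dx^3 returns Q/8:
        the cube of the kernel's per-axis self-overlap 1/2."""
        pts = np.array([[0.4 * grid.lx, 0.6 * grid.ly, 0.5 * grid.lz]])
        q = spread_scalar(np.array([1.0]), np.array([grid.cell_volume]),
                          pts, grid)
        back = interpolate_scalar(q, pts, grid)[0]
        assert back == pytest.approx(0.125, rel=1e-10)

    def test_translation_invariance_periodic_axis(self, grid):
        pts = np.array([[0.4 * grid.lx, 0.6 * grid.ly, 0.5 * grid.lz]])
        q1 = spread_scalar(np.array([1.0]), np.array([1.0]), pts, grid)
        pts2 = pts + np.array([[grid.dx, 0, 0]])
        q2 = spread_scalar(np.array([1.0]), np.array([1.0]), pts2, grid)
        assert np.allclose(np.roll(q1, 1, axis=0), q2, atol=1e-18)


class TestStaggered:
    def test_velocity_interpolation_of_uniform_flow(self, grid):
        u = np.full(grid.shape, 2.0)
        v = np.full(grid.shape, -1.0)
        w = np.zeros((grid.nx, grid.ny, grid.nz + 1))
        pts = np.array([[0.3 * grid.lx, 0.7 * grid.ly, 0.5 * grid.lz]])
        vel = interpolate_velocity(u, v, w, pts, grid)
        assert np.allclose(vel, [[2.0, -1.0, 0.0]], atol=1e-12)

    def test_force_spreading_conserves_momentum_input(self, grid):
        rng = np.random.default_rng(3)
        pts = rng.uniform([0, 0, 3 * grid.dx],
                          [grid.lx, grid.ly, grid.lz - 3 * grid.dx], (40, 3))
        F = rng.normal(size=(40, 3))
        dV = np.full(40, grid.cell_volume)
        fu, fv, fw = spread_force(F, dV, pts, grid)
        assert fu.sum() * grid.cell_volume == pytest.approx(
            (F[:, 0] * dV).sum(), rel=1e-12)
        assert fw.sum() * grid.cell_volume == pytest.approx(
            (F[:, 2] * dV).sum(), rel=1e-12)
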