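"""Voxelization, 3D Zernike moments vs direct integration, invariance."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y

from tcrdyn import TrajectoryError
from tcrdyn.zernike import (
    VoxelGrid,
    coulomb_potential,
    descriptor_distance,
    surface_voxels,
    voxelize_electrostatics,
    voxelize_shape,
    zernike_invariants,
    zernike_moments,
    _radial_poly,
)


def direct_moments(grid, order):
    """Slow per-voxel loop evaluating the basis-integration definition."""
    m_side = grid.side
    axis = (np.arange(m_side) + 0.5) * 2.0 / m_side - 1.0
    dv = (2.0 / m_side) ** 3
    out = {}
    for l in range(order + 1):
        for n in range(l, order + 1, 2):
            vals = np.zeros(2 * l + 1, dtype=complex)
            for ix in range(m_side):
                for iy in range(m_side):
                    for iz in range(m_side):
                        f = grid.values[ix, iy, iz]
                        if f == 0:
                            continue
                        x, y, z = axis[ix], axis[iy], axis[iz]
                        r = np.sqrt(x * x + y * y + z * z)
                        if r > 1:
                            continue
                        theta = np.arccos(z / r) if r > 1e-12 else 0.0
                        phi = np.arctan2(y, x)
                        rad = _radial_poly(n, l, np.array([r]))[0]
                        for m in range(-l, l + 1):
                            y_lm = sph_harm_y(l, m, theta, phi)
                            vals[m + l] += f * rad * np.conj(y_lm)
            out[(n, l)] = 3.0 / (4 * np.pi) * dv * vals
    return out


class TestVoxelize:
    def test_single_atom_volume_within_5_percent(self):
        g = voxelize_shape(np.zeros((1, 3)), radii=[0.2], grid_side=64, probe=0.0)
        vol = g.values.sum() * (2.0 / 64) ** 3 / g.scale**3
        true = 4.0 / 3.0 * np.pi * 0.2**3
        assert abs(vol - true) / true < 0.05

    def test_empty_selection_rejected(self):
        with pytest.raises(TrajectoryError):
            voxelize_shape(np.zeros((0, 3)))

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 3))
        g1 = voxelize_shape(pts, grid_side=32)
        g2 = voxelize_shape(pts + np.array([10.0, -4.0, 2.0]), grid_side=32)
        np.testing.assert_array_equal(g1.values, g2.values)

    def test_content_inside_unit_ball(self):
        rng = np.random.default_rng(2)
        g = voxelize_shape(rng.normal(size=(10, 3)), grid_side=32)
        centers = g.voxel_centers_unit()[g.values > 0]
        assert np.all(np.linalg.norm(centers, axis=1) <= 1.0)


class TestElectrostatics:
    def test_positive_charge_empty_negative_channel(self):
        pos, neg = voxelize_electrostatics(
            np.zeros((1, 3)), charges=[1.0], grid_side=32
        )
        assert np.all(neg.values == 0)
        assert pos.values.sum() > 0

    def test_dipole_splits_hemispheres(self):
        coords = np.array([[-0.3, 0, 0], [0.3, 0, 0]])
        pos, neg = voxelize_electrostatics(coords, charges=[1.0, -1.0], grid_side=32)
        assert pos.values.sum() > 0 and neg.values.sum() > 0
        # positive potential concentrates on the +charge side (-x here)
        m = pos.side
        assert pos.values[: m // 2].sum() > pos.values[m // 2:].sum()
        assert neg.values[m // 2:].sum() > neg.values[: m // 2].sum()

    def test_coulomb_falls_off_as_one_over_r(self):
        pts = np.array([[r, 0.0, 0.0] for r in (0.5, 1.0, 2.0, 4.0)])
        phi = coulomb_potential(pts, np.zeros((1, 3)), [1.0])
        np.testing.assert_allclose(phi * pts[:, 0], phi[1] * 1.0, rtol=1e-12)

    def test_no_charge_source_rejected(self):
        with pytest.raises(TrajectoryError, match="charge source"):
            voxelize_electrostatics(np.zeros((1, 3)))

    def test_external_potential_nearest_neighbour(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(scale=0.5, size=(200, 3))
        vals = np.full(200, 2.5)
        pos, neg = voxelize_electrostatics(
            np.zeros((2, 3)) + [[0, 0, 0], [0.3, 0, 0]],
            external_potential=(pts, vals),
            grid_side=16,
        )
        surf = surface_voxels(
            voxelize_shape(np.array([[0, 0, 0], [0.3, 0, 0]]), grid_side=16)
        )
        assert np.all(pos.values[surf] == 2.5)
        assert np.all(neg.values == 0)


class TestMoments:
    def test_zero_grid_zero_moments(self):
        g = VoxelGrid(np.zeros((8, 8, 8)), "shape", np.zeros(3), 1.0)
        mom = zernike_moments(g, order=4)
        for arr in mom.data.values():
            np.testing.assert_array_equal(arr, 0)

    def test_centered_ball_only_l0(self):
        g = voxelize_shape(np.zeros((1, 3)), radii=[0.25], grid_side=64, probe=0.0)
        desc = zernike_invariants(zernike_moments(g, order=8))
        vals = dict(zip(desc.index, desc.values))
        peak = max(vals.values())
        for (n, l), v in vals.items():
            if l != 0:
                assert v < 0.01 * peak

    def test_matches_direct_integration_oracle(self):
        """Vectorized moments equal the slow triple-loop basis integration."""
        rng = np.random.default_rng(4)
        pts = rng.normal(scale=0.3, size=(4, 3))
        g = voxelize_shape(pts, radii=[0.15] * 4, grid_side=16, probe=0.0)
        mom = zernike_moments(g, order=6)
        oracle = direct_moments(g, 6)
        for key in oracle:
            np.testing.assert_allclose(mom.data[key], oracle[key], atol=1e-6)

    def test_conjugation_symmetry(self):
        rng = np.random.default_rng(5)
        g = voxelize_shape(rng.normal(scale=0.3, size=(6, 3)), grid_side=16)
        mom = zernike_moments(g, order=6)
        for (n, l), arr in mom.data.items():
            for m in range(1, l + 1):
                assert arr[l - m] == pytest.approx(
                    (-1) ** m * np.conj(arr[l + m]), abs=1e-12
                )

    def test_content_outside_ball_rejected(self):
        v = np.zeros((8, 8, 8))
        v[0, 0, 0] = 1.0  # corner voxel, r > 1
        g = VoxelGrid(v, "shape", np.zeros(3), 1.0)
        with pytest.raises(TrajectoryError, match="unit ball"):
            zernike_moments(g, order=2)


class TestInvariants:
    def test_zero_moments_zero_descriptor(self):
        g = VoxelGrid(np.zeros((8, 8, 8)), "shape", np.zeros(3), 1.0)
        desc = zernike_invariants(zernike_moments(g, order=4))
        np.testing.assert_array_equal(desc.values, 0)

    def test_axis_aligned_rotation_exact(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(scale=0.3, size=(8, 3))
        d1 = zernike_invariants(zernike_moments(voxelize_shape(pts, grid_side=32), 8))
        rot = pts @ np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1.0]]).T  # 90 deg about z
        d2 = zernike_invariants(zernike_moments(voxelize_shape(rot, grid_side=32), 8))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-10)

    def test_arbitrary_rotation_small_change(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(scale=0.4, size=(10, 3))
        radii = rng.uniform(0.12, 0.22, size=10)
        d1 = zernike_invariants(
            zernike_moments(voxelize_shape(pts, radii=radii, grid_side=64), 12)
        )
        rot = Rotation.from_euler("zyx", [0.4, 1.1, -0.7]).as_matrix()
        d2 = zernike_invariants(
            zernike_moments(voxelize_shape(pts @ rot.T, radii=radii, grid_side=64), 12)
        )
        rel = np.linalg.norm(d1.values - d2.values) / np.linalg.norm(d1.values)
        assert rel < 0.01


class TestDistance:
    def _descriptor(self, pts, radii=None, side=32, order=8):
        return zernike_invariants(
            zernike_moments(voxelize_shape(pts, radii=radii, grid_side=side), order)
        )

    def test_identical_zero(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(5, 3))
        assert descriptor_distance(self._descriptor(pts), self._descriptor(pts)) == 0.0

    def test_shape_change_beats_rotation(self):
        """Sphere vs ellipsoid differ more than sphere vs rotated sphere."""
        sphere = np.zeros((1, 3))
        ellipsoid = np.array([[x, 0.0, 0.0] for x in np.linspace(-0.3, 0.3, 7)])
        rot = Rotation.from_euler("xyz", [0.3, 0.2, 0.9]).as_matrix()
        d_sphere = self._descriptor(sphere, radii=[0.25])
        d_ell = self._descriptor(ellipsoid, radii=[0.25] * 7)
        d_rot = self._descriptor(ellipsoid @ rot.T, radii=[0.25] * 7)
        assert descriptor_distance(d_sphere, d_ell) > descriptor_distance(d_ell, d_rot)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(9)
        ds = [self._descriptor(rng.normal(scale=0.3, size=(6, 3))) for _ in range(3)]
        a = descriptor_distance(ds[0], ds[1])
        b = descriptor_distance(ds[1], ds[2])
        c = descriptor_distance(ds[0], ds[2])
        assert c <= a + b + 1e-12

    def test_mismatched_order_rejected(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(4, 3))
        d1 = self._descriptor(pts, order=6)
        d2 = self._descriptor(pts, order=8)
        with pytest.raises(TrajectoryError):
            descriptor_distance(d1, d2)
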