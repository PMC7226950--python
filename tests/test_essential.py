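"""Covariance analysis, eigen-decomposition, projections, common subspaces."""

import numpy as np
import pytest

from tcrdyn import Ensemble, TrajectoryError
from tcrdyn.essential import (
    combined_subspace,
    covariance_matrix,
    diagonalize,
    essential_subspace,
    project,
    subspace_overlap,
    variance_fraction,
)
from tcrdyn.synthetic import ModeSpec, make_toy_complex, sample_ensemble


@pytest.fixture(scope="module")
def tiny():
    return make_toy_complex(
        {"groove": 4, "Valpha": 3, "Vbeta": 3, "Calpha": 3, "Cbeta": 3}, "SLL", seed=2
    )


class TestCovariance:
    def test_static_ensemble_zero_matrix(self, tiny):
        top, ref = tiny
        ens = Ensemble(top, np.repeat(ref[None], 3, axis=0))
        cov = covariance_matrix(ens, fit=False)
        np.testing.assert_allclose(cov, 0.0, atol=1e-14)

    def test_two_frame_one_coordinate_variance(self, tiny):
        top, ref = tiny
        d = 0.3
        lo, hi = ref.copy(), ref.copy()
        lo[0, 0] -= d
        hi[0, 0] += d
        ens = Ensemble(top, np.stack([lo, hi]))
        cov = covariance_matrix(ens, fit=False)
        assert np.isclose(cov[0, 0], d**2)
        cov[0, 0] = 0.0
        np.testing.assert_allclose(cov, 0.0, atol=1e-14)

    def test_gaussian_fixture_matches_target(self, tiny):
        top, ref = tiny
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.normal(size=(3 * top.n_atoms, 2)))
        spec = ModeSpec(modes=[(q[:, 0], 0.5), (q[:, 1], 0.2)], epsilon=1e-4)
        ens = sample_ensemble(top, ref, spec, 50_000, seed=4)
        cov = covariance_matrix(ens, fit=False)
        target = spec.covariance(3 * top.n_atoms)
        assert np.max(np.abs(cov - target)) < 0.02 * 0.5


class TestDiagonalize:
    def test_diagonal_input(self):
        d = np.diag([3.0, 1.0, 2.0, 0.5, 0.1, 0.0])
        space = diagonalize(d)
        np.testing.assert_allclose(space.eigenvalues, [3.0, 2.0, 1.0, 0.5, 0.1, 0.0])

    def test_rank_one(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=12)
        v /= np.linalg.norm(v)
        space = diagonalize(2.5 * np.outer(v, v))
        assert np.isclose(space.eigenvalues[0], 2.5)
        np.testing.assert_allclose(space.eigenvalues[1:], 0.0, atol=1e-12)

    def test_matches_characteristic_polynomial_roots(self):
        """Eigenvalues agree with an independent char-poly root finder."""
        rng = np.random.default_rng(6)
        a = rng.normal(size=(12, 12))
        psd = a @ a.T / 12
        space = diagonalize(psd)
        roots = np.sort(np.roots(np.poly(psd)).real)[::-1]
        np.testing.assert_allclose(space.eigenvalues, roots, rtol=1e-6, atol=1e-8)

    def test_reconstruction(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(9, 9))
        psd = a @ a.T
        space = diagonalize(psd)
        rec = space.eigenvectors @ np.diag(space.eigenvalues) @ space.eigenvectors.T
        np.testing.assert_allclose(rec, psd, atol=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(TrajectoryError, match="symmetric"):
            diagonalize(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_trace_conservation(self, gaussian_ensemble):
        space = essential_subspace(gaussian_ensemble, fit=False)
        assert abs(space.eigenvalues.sum() - space.trace) <= 1e-8 * space.trace


class TestVarianceFraction:
    def test_flat_spectrum(self):
        space = diagonalize(np.eye(6))
        assert np.isclose(variance_fraction(space, 1), 1 / 6)

    def test_rank_one_full(self):
        v = np.zeros(6)
        v[0] = 1.0
        space = diagonalize(np.outer(v, v))
        assert variance_fraction(space, 1) == 1.0

    def test_zero_total_warns(self):
        space = diagonalize(np.zeros((6, 6)))
        with pytest.warns(UserWarning):
            assert variance_fraction(space, 2) == 0.0

    def test_two_dominant_modes_recovered(self, toy_complex):
        top, ref = toy_complex
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(3 * top.n_atoms, 2)))
        spec = ModeSpec(modes=[(q[:, 0], 1.0), (q[:, 1], 1.0)], epsilon=1e-5)
        ens = sample_ensemble(top, ref, spec, 20_000, seed=9)
        space = essential_subspace(ens, fit=False)
        planted = 2.0 / (2.0 + 1e-5 * 3 * top.n_atoms)
        assert abs(variance_fraction(space, 2) - planted) < 0.02


class TestProject:
    def test_variance_identity(self, gaussian_ensemble):
        """Sample variance along eigenvector k equals lambda_k exactly."""
        space = essential_subspace(gaussian_ensemble)
        proj = project(gaussian_ensemble, space, k=5)
        var = proj.coords.var(axis=0, ddof=0)
        np.testing.assert_allclose(var, space.eigenvalues[:5], rtol=1e-6)

    def test_mean_projects_to_origin(self, gaussian_ensemble):
        space = essential_subspace(gaussian_ensemble, fit=False)
        top = gaussian_ensemble.topology
        ens1 = Ensemble(top, np.stack([space.mean, space.mean]))
        proj = project(ens1, space, k=2)
        np.testing.assert_allclose(proj.coords, 0.0, atol=1e-10)

    def test_frame_along_first_eigenvector(self, gaussian_ensemble):
        space = essential_subspace(gaussian_ensemble, fit=False)
        c = 0.37
        frame = space.mean.reshape(-1) + c * space.eigenvectors[:, 0]
        top = gaussian_ensemble.topology
        ens1 = Ensemble(top, np.repeat(frame.reshape(1, -1, 3), 2, axis=0))
        proj = project(ens1, space, k=2)
        np.testing.assert_allclose(proj.coords[0], [c, 0.0], atol=1e-10)

    def test_atom_count_mismatch(self, gaussian_ensemble, tiny):
        space = essential_subspace(gaussian_ensemble, fit=False)
        top, ref = tiny
        ens = Ensemble(top, ref[None].repeat(2, axis=0))
        with pytest.raises(TrajectoryError, match="atoms"):
            project(ens, space)


class TestCombined:
    def test_identical_systems_identical_projections(self, gaussian_ensemble):
        space, projs = combined_subspace(
            [gaussian_ensemble, gaussian_ensemble], systems=["a", "b"]
        )
        np.testing.assert_allclose(projs[0].coords, projs[1].coords, atol=1e-10)
        assert subspace_overlap(projs[0], projs[1]) == 1.0

    def test_mean_shift_dominates_first_eigenvector(self, tiny):
        """Between-system separation loads onto the leading common mode."""
        top, ref = tiny
        n_dof = 3 * top.n_atoms
        rng = np.random.default_rng(12)
        v = rng.normal(size=n_dof)
        v /= np.linalg.norm(v)
        spec = ModeSpec(modes=[], epsilon=1e-4)
        e1 = sample_ensemble(top, ref, spec, 300, seed=13)
        shift = 2.0 * v.reshape(-1, 3)
        e2 = sample_ensemble(top, ref + shift, spec, 300, seed=14)
        space, projs = combined_subspace([e1, e2], systems=["bound", "unbound"], fit=False)
        align = abs(np.dot(space.eigenvectors[:, 0], v))
        assert align > 0.99
        # the two clouds separate along PC1
        assert abs(projs[0].coords[:, 0].mean() - projs[1].coords[:, 0].mean()) > 1.0
        assert subspace_overlap(projs[0], projs[1]) < 0.05

    def test_disjoint_modes_separate_more_than_shared_modes(self, tiny):
        top, ref = tiny
        n_dof = 3 * top.n_atoms
        rng = np.random.default_rng(15)
        q, _ = np.linalg.qr(rng.normal(size=(n_dof, 2)))
        sa = ModeSpec(modes=[(q[:, 0], 0.5)], epsilon=1e-5)
        sb = ModeSpec(modes=[(q[:, 1], 0.5)], epsilon=1e-5)
        ea = sample_ensemble(top, ref, sa, 400, seed=16)
        eb = sample_ensemble(top, ref, sb, 400, seed=17)
        eb_same = sample_ensemble(top, ref, sa, 400, seed=18)
        _, p_diff = combined_subspace([ea, eb], systems=["a", "b"], fit=False)
        _, p_same = combined_subspace([ea, eb_same], systems=["a", "b"], fit=False)
        assert subspace_overlap(*p_diff) < subspace_overlap(*p_same)

    def test_unequal_atom_counts_named(self, gaussian_ensemble, tiny):
        top, ref = tiny
        ens = Ensemble(top, ref[None].repeat(3, axis=0))
        with pytest.raises(TrajectoryError, match="differ"):
            combined_subspace([gaussian_ensemble, ens], systems=["big", "small"])


class TestOverlap:
    def test_disjoint_clouds_zero(self):
        from tcrdyn.essential import Projection2D

        a = Projection2D(np.random.default_rng(0).normal(size=(100, 2)), "a", "s")
        b = Projection2D(a.coords + 100.0, "b", "s")
        assert subspace_overlap(a, b) == 0.0

    def test_matches_independent_grid_estimate(self):
        """Jaccard cell overlap agrees with a from-scratch re-count."""
        from tcrdyn.essential import Projection2D

        rng = np.random.default_rng(19)
        pa = rng.normal(size=(500, 2))
        pb = rng.normal(size=(500, 2)) + [1.0, 0.0]
        a = Projection2D(pa, "a", "s")
        b = Projection2D(pb, "b", "s")
        got = subspace_overlap(a, b, n_cells=50)

        allp = np.vstack([pa, pb])
        lo, hi = allp.min(axis=0), allp.max(axis=0)
        def occupied(p):
            cells = set()
            for x, y in p:
                i = min(int((x - lo[0]) / (hi[0] - lo[0]) * 50), 49)
                j = min(int((y - lo[1]) / (hi[1] - lo[1]) * 50), 49)
                cells.add((i, j))
            return cells
        ca, cb = occupied(pa), occupied(pb)
        expected = len(ca & cb) / len(ca | cb)
        assert got == pytest.approx(expected)

    def test_mismatched_subspace_rejected(self):
        from tcrdyn.essential import Projection2D

        a = Projection2D(np.zeros((3, 2)), "a", "s1")
        b = Projection2D(np.zeros((3, 2)), "b", "s2")
        with pytest.raises(TrajectoryError):
            subspace_overlap(a, b)
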