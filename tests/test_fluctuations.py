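"""Superposition, RMSD and RMSF against closed forms and brute-force oracles."""

import numpy as np
import pytest

from tcrdyn import Ensemble, TrajectoryError
from tcrdyn.fluctuations import rmsd_series, rmsf_by_residue, rmsf_profile, superpose
from tcrdyn.synthetic import make_toy_complex


def brute_rmsd(frame, ref, idx):
    """Independent double-loop evaluation of the RMSD definition."""
    s = 0.0
    for i in idx:
        d = frame[i] - ref[i]
        s += d[0] ** 2 + d[1] ** 2 + d[2] ** 2
    return (s / len(idx)) ** 0.5


def brute_rmsf(coords, ref, idx):
    out = []
    for i in idx:
        s = 0.0
        for t in range(len(coords)):
            d = coords[t, i] - ref[i]
            s += d[0] ** 2 + d[1] ** 2 + d[2] ** 2
        out.append((s / len(coords)) ** 0.5)
    return np.array(out)


@pytest.fixture(scope="module")
def ten_atoms():
    rng = np.random.default_rng(21)
    return rng.normal(size=(10, 3))


class TestSuperpose:
    def test_identity(self, ten_atoms):
        tr, moved = superpose(ten_atoms, ten_atoms)
        np.testing.assert_allclose(moved, ten_atoms, atol=1e-12)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-10)
        assert np.isclose(np.linalg.det(tr.rotation), 1.0)

    def test_pure_translation_recovered(self, ten_atoms):
        shifted = ten_atoms + np.array([1.0, 2.0, 3.0])
        _, moved = superpose(shifted, ten_atoms)
        np.testing.assert_allclose(moved, ten_atoms, atol=1e-12)

    def test_residual_matches_rotation_grid_search(self, ten_atoms):
        """Kabsch residual is not beaten by a fine brute-force rotation grid."""
        rng = np.random.default_rng(22)
        other = ten_atoms + rng.normal(scale=0.3, size=ten_atoms.shape)
        _, moved = superpose(other, ten_atoms)
        best = np.sum((moved - ten_atoms) ** 2)

        a0 = other - other.mean(axis=0)
        b0 = ten_atoms - ten_atoms.mean(axis=0)
        angles = np.linspace(0, 2 * np.pi, 25, endpoint=False)

        def rot(ax, ay, az):
            cx, sx = np.cos(ax), np.sin(ax)
            cy, sy = np.cos(ay), np.sin(ay)
            cz, sz = np.cos(az), np.sin(az)
            rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
            ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
            rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
            return rz @ ry @ rx

        grid_best = min(
            np.sum((a0 @ rot(ax, ay, az).T - b0) ** 2)
            for ax in angles
            for ay in angles[:13]
            for az in angles
        )
        assert best <= grid_best + 1e-9

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(TrajectoryError, match="collinear"):
            superpose(line, line + 1.0)


def _static_ensemble(top, ref, n=4):
    return Ensemble(top, np.repeat(ref[None], n, axis=0))


@pytest.fixture(scope="module")
def toy():
    return make_toy_complex(
        {"groove": 4, "Valpha": 3, "Vbeta": 3, "Calpha": 3, "Cbeta": 3}, "SLL", seed=2
    )


class TestRmsd:
    def test_copies_of_reference_give_zero(self, toy):
        top, ref = toy
        series = rmsd_series(_static_ensemble(top, ref), fit=False)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-14)

    def test_single_displaced_atom_closed_form(self, toy):
        top, ref = toy
        frame = ref.copy()
        d = 0.7
        frame[3, 0] += d
        ens = Ensemble(top, np.stack([ref, frame]))
        series = rmsd_series(ens, fit=False)
        np.testing.assert_allclose(series.values[1], d / np.sqrt(top.n_atoms), rtol=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(33)
        from tcrdyn.model import Topology

        n = 10
        top = Topology(
            names=np.array(["CA"] * n, dtype=object),
            elements=np.array(["C"] * n, dtype=object),
            resindices=np.arange(n),
            resids=np.arange(1, n + 1),
            resnames=np.array(["GLY"] * n, dtype=object),
            chains=np.array(["A"] * n, dtype=object),
        )
        coords = rng.normal(size=(100, n, 3))
        ens = Ensemble(top, coords)
        series = rmsd_series(ens, fit=False)
        expected = [brute_rmsd(coords[t], coords[0], range(n)) for t in range(100)]
        np.testing.assert_allclose(series.values, expected, rtol=1e-10)

    def test_fit_never_increases_rmsd(self, toy):
        top, ref = toy
        rng = np.random.default_rng(8)
        coords = ref[None] + rng.normal(scale=0.05, size=(20, top.n_atoms, 3))
        ens = Ensemble(top, coords)
        fitted = rmsd_series(ens, fit=True).values
        raw = rmsd_series(ens, fit=False).values
        assert np.all(fitted <= raw + 1e-12)


class TestRmsf:
    def test_static_is_zero(self, toy):
        top, ref = toy
        prof = rmsf_profile(_static_ensemble(top, ref), fit=False)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-14)

    def test_alternating_atom_closed_form(self, toy):
        top, ref = toy
        d = 0.4
        hi = ref.copy()
        hi[0, 0] += d
        ens = Ensemble(top, np.stack([ref, hi, ref, hi]))
        prof = rmsf_profile(ens, reference_mode="initial", fit=False)
        np.testing.assert_allclose(prof.values[0], d / np.sqrt(2), rtol=1e-12)
        np.testing.assert_allclose(prof.values[1:], 0.0, atol=1e-14)

    def test_gaussian_sigma_sqrt3(self, toy):
        """Isotropic per-atom noise sigma gives RMSF -> sigma * sqrt(3)."""
        top, ref = toy
        sigma = 0.2
        rng = np.random.default_rng(9)
        coords = ref[None] + rng.normal(scale=sigma, size=(20000, top.n_atoms, 3))
        ens = Ensemble(top, coords)
        prof = rmsf_profile(ens, reference_mode="mean", fit=False)
        np.testing.assert_allclose(prof.values, sigma * np.sqrt(3), rtol=0.05)

    def test_mean_mode_never_exceeds_initial_mode(self, toy):
        top, ref = toy
        rng = np.random.default_rng(10)
        coords = ref[None] + rng.normal(scale=0.1, size=(50, top.n_atoms, 3))
        coords += rng.normal(scale=0.05, size=(50, 1, 3))  # drift
        ens = Ensemble(top, coords)
        mean = rmsf_profile(ens, reference_mode="mean", fit=False).values
        init = rmsf_profile(ens, reference_mode="initial", fit=False).values
        assert np.all(mean <= init + 1e-12)

    def test_matches_brute_force(self, toy):
        top, ref = toy
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(100, top.n_atoms, 3))
        ens = Ensemble(top, coords)
        prof = rmsf_profile(ens, reference_mode="initial", fit=False)
        np.testing.assert_allclose(
            prof.values, brute_rmsf(coords, coords[0], range(top.n_atoms)), rtol=1e-10
        )

    def test_residue_aggregation(self, toy):
        top, ref = toy
        rng = np.random.default_rng(12)
        coords = ref[None] + rng.normal(scale=0.05, size=(10, top.n_atoms, 3))
        ens = Ensemble(top, coords)
        prof = rmsf_profile(ens, fit=False)
        res, vals = rmsf_by_residue(ens, prof)
        assert len(res) == top.n_residues  # one bead per residue here
        np.testing.assert_allclose(vals, prof.values)
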