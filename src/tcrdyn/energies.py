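"""Nonbonded region-pair interaction energies (Coulomb + Lennard-Jones).

Coulomb = sum f q_i q_j / (eps_r r_ij) and
LJ = sum 4 eps_ij [(sigma_ij/r_ij)^12 - (sigma_ij/r_ij)^6]
over cross pairs within a plain distance cutoff (default 1.2 nm, the
production-run nonbonded cutoff), with Lorentz-Berthelot combination
rules. f = 138.935 kJ mol^-1 nm e^-2. This is a descriptive statistic of
region-region coupling, not a dynamics driver, so no Ewald summation or
exclusions are applied (the analysed regions are never covalently
bonded to each other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Ensemble, Topology, TrajectoryError, as_indices

__all__ = [
    "COULOMB_PREFACTOR",
    "DEFAULT_CUTOFF_NM",
    "NonbondedParams",
    "toy_params",
    "pair_energy",
    "energy_series",
    "energy_distribution",
]

COULOMB_PREFACTOR = 138.935  # kJ mol^-1 nm e^-2
DEFAULT_CUTOFF_NM = 1.2
CLASH_DISTANCE_NM = 0.01


@dataclass
class NonbondedParams:
    """Per-atom charge (e), LJ sigma (nm) and epsilon (kJ/mol).

    Lookup by (resname, atom name) with an atom-name fallback. Build from
    a whitespace table via :meth:`from_table`.
    """

    by_residue_atom: dict = field(default_factory=dict)  # (resname, name) -> (q, sigma, eps)
    by_atom: dict = field(default_factory=dict)  # name -> (q, sigma, eps)

    def lookup(self, resname: str, name: str):
        key = (str(resname), str(name))
        if key in self.by_residue_atom:
            q, s, e = self.by_residue_atom[key]
        elif str(name) in self.by_atom:
            q, s, e = self.by_atom[str(name)]
        else:
            raise TrajectoryError(f"no nonbonded parameters for {resname}/{name}")
        if s <= 0 or e < 0:
            raise TrajectoryError(f"invalid LJ parameters for {resname}/{name}")
        return float(q), float(s), float(e)

    def arrays(self, topology: Topology, idx: np.ndarray):
        q = np.empty(len(idx))
        s = np.empty(len(idx))
        e = np.empty(len(idx))
        for k, i in enumerate(idx):
            q[k], s[k], e[k] = self.lookup(topology.resnames[i], topology.names[i])
        return q, s, e

    @staticmethod
    def from_table(path) -> "NonbondedParams":
        """Parse a whitespace table: ``resname atomname charge sigma epsilon``.

        A resname of ``*`` declares an atom-name fallback row. Lines
        starting with ``#`` are comments.
        """
        p = NonbondedParams()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 5:
                    raise TrajectoryError(f"bad parameter line: {line!r}")
                resname, name, q, s, e = parts
                rec = (float(q), float(s), float(e))
                if resname == "*":
                    p.by_atom[name] = rec
                else:
                    p.by_residue_atom[(resname, name)] = rec
        return p


def toy_params() -> NonbondedParams:
    """Bundled pseudo-atom parameter set for synthetic fixtures.

    Single-bead residues get a small negative charge and generic
    carbon-like LJ parameters; headgroup and donor/acceptor pseudo-atoms
    get modest polar charges. Not a force field — a self-consistent toy.
    """
    p = NonbondedParams()
    p.by_atom = {
        "CA": (-0.1, 0.34, 0.36),
        "N": (-0.3, 0.325, 0.71),
        "O": (-0.5, 0.296, 0.88),
        "P": (-0.8, 0.374, 0.80),
    }
    return p


def pair_energy(
    ensemble: Ensemble,
    frame: int,
    selection_a,
    selection_b,
    params: NonbondedParams,
    cutoff: float = DEFAULT_CUTOFF_NM,
    dielectric: float = 1.0,
):
    """(Coulomb, LJ) interaction energy in kJ/mol between two disjoint regions.

    Atom pairs closer than 0.01 nm trigger a clash warning but the energy
    is still reported.
    """
    import warnings

    top = ensemble.topology
    ia = as_indices(top, selection_a)
    ib = as_indices(top, selection_b)
    if len(ia) == 0 or len(ib) == 0:
        raise TrajectoryError("empty selection")
    if set(ia.tolist()) & set(ib.tolist()):
        raise TrajectoryError("selections overlap; region pairs must be disjoint")
    qa, sa, ea = params.arrays(top, ia)
    qb, sb, eb = params.arrays(top, ib)
    pa = ensemble.coords[frame, ia, :]
    pb = ensemble.coords[frame, ib, :]
    diff = pa[:, None, :] - pb[None, :, :]
    if ensemble.box is not None:
        box = ensemble.box[frame, :3]
        diff = diff - box * np.round(diff / box)
    r = np.sqrt(np.sum(diff**2, axis=2))
    if np.any(r < CLASH_DISTANCE_NM):
        warnings.warn(
            f"{int(np.sum(r < CLASH_DISTANCE_NM))} atom pairs closer than "
            f"{CLASH_DISTANCE_NM} nm (clash)",
            stacklevel=2,
        )
    mask = r < cutoff
    if not mask.any():
        return 0.0, 0.0
    rr = r[mask]
    qq = np.outer(qa, qb)[mask]
    coulomb = float(np.sum(COULOMB_PREFACTOR * qq / (dielectric * rr)))
    # Lorentz-Berthelot: sigma arithmetic mean, epsilon geometric mean
    sij = (0.5 * (sa[:, None] + sb[None, :]))[mask]
    eij = np.sqrt(np.outer(ea, eb))[mask]
    sr6 = (sij / rr) ** 6
    lj = float(np.sum(4.0 * eij * (sr6**2 - sr6)))
    return coulomb, lj


def energy_series(
    ensemble: Ensemble,
    selection_a,
    selection_b,
    params: NonbondedParams,
    cutoff: float = DEFAULT_CUTOFF_NM,
    dielectric: float = 1.0,
) -> pd.DataFrame:
    """Per-frame Coulomb/LJ/total energies between two regions."""
    rows = []
    for t in range(ensemble.n_frames):
        c, lj = pair_energy(ensemble, t, selection_a, selection_b, params, cutoff, dielectric)
        rows.append((t, c, lj, c + lj))
    return pd.DataFrame(rows, columns=["frame", "coulomb", "lj", "total"])


def energy_distribution(
    ensemble: Ensemble,
    region_pairs,
    params: NonbondedParams,
    cutoff: float = DEFAULT_CUTOFF_NM,
    dielectric: float = 1.0,
    bins: int = 50,
):
    """Energy series + histogram per region pair.

    ``region_pairs`` is an iterable of (region_a, region_b) names, e.g.
    (peptide, groove), (peptide, TCR), (TCR, groove). Returns a dict
    mapping the pair to {'series', 'hist_counts', 'hist_edges', 'mean',
    'mode'} where 'mode' is the midpoint of the fullest histogram bin.
    """
    out = {}
    for a, b in region_pairs:
        series = energy_series(ensemble, a, b, params, cutoff, dielectric)
        tot = series["total"].to_numpy()
        counts, edges = np.histogram(tot, bins=bins)
        mode_bin = int(np.argmax(counts))
        out[(a, b)] = {
            "series": series,
            "hist_counts": counts,
            "hist_edges": edges,
            "mean": float(tot.mean()),
            "mode": float(0.5 * (edges[mode_bin] + edges[mode_bin + 1])),
        }
    return out
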