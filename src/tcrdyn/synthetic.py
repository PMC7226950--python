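"""Ground-truth synthetic systems: toy pMHC-TCR complexes, Gaussian
ensembles with prescribed covariance, lipid bilayers, and hydrogen-bond
geometries.

Every generator is a pure function of (spec, seed). The planted parameters
(mode amplitudes, region correlations, leaflet separation, H-bond
occupancies) are exactly the quantities the analysis modules are meant to
recover, which makes the generators the oracle for the whole test suite.

Fluctuations are multivariate Gaussian: essential dynamics and
cross-correlation are second-moment methods, so Gaussian ensembles
exercise them completely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Ensemble, Topology, TrajectoryError

__all__ = [
    "ModeSpec",
    "BilayerSpec",
    "make_toy_complex",
    "sample_ensemble",
    "sample_correlated_regions",
    "make_bilayer",
    "make_hbond_trajectory",
    "DEFAULT_REGION_SIZES",
]

#: Default residue counts per region for a desk-scale toy complex. The
#: groove uses the study's definition (residues 1-175 of the HLA alpha
#: chain); the TCR domains use typical Ig-domain lengths.
DEFAULT_REGION_SIZES = {
    "groove": 175,
    "Valpha": 110,
    "Vbeta": 115,
    "Calpha": 90,
    "Cbeta": 130,
}

# one chain id per region so file round-trips can re-declare regions
# unambiguously by chain + resid range
_REGION_CHAINS = {
    "groove": "A",
    "peptide": "C",
    "Valpha": "D",
    "Vbeta": "E",
    "Calpha": "F",
    "Cbeta": "G",
}

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass
class ModeSpec:
    """Prescription for the covariance of a Gaussian ensemble.

    ``modes`` is a list of (direction, amplitude) pairs: direction vectors
    of length 3N, mutually orthonormal; amplitudes in nm^2, sorted
    descending. The target population covariance is
    ``sum_k a_k v_k v_k^T + epsilon * I``.
    """

    modes: list = field(default_factory=list)
    epsilon: float = 0.0

    def validate(self, n_dof: int) -> None:
        amps = [a for _, a in self.modes]
        if any(a < 0 for a in amps):
            raise TrajectoryError("mode amplitudes must be >= 0")
        if sorted(amps, reverse=True) != amps:
            raise TrajectoryError("mode amplitudes must be sorted descending")
        if self.epsilon < 0:
            raise TrajectoryError("epsilon must be >= 0")
        vecs = [np.asarray(v, dtype=float) for v, _ in self.modes]
        for v in vecs:
            if v.shape != (n_dof,):
                raise TrajectoryError(f"mode vectors must have length {n_dof}")
        for i, v in enumerate(vecs):
            for j, w in enumerate(vecs):
                want = 1.0 if i == j else 0.0
                if abs(float(v @ w) - want) > 1e-8:
                    raise TrajectoryError(f"mode vectors {i},{j} are not orthonormal")

    def covariance(self, n_dof: int) -> np.ndarray:
        """The exact population covariance this spec prescribes (3N x 3N)."""
        sigma = self.epsilon * np.eye(n_dof)
        for v, a in self.modes:
            v = np.asarray(v, dtype=float)
            sigma += a * np.outer(v, v)
        return sigma


@dataclass
class BilayerSpec:
    """Prescription for a two-leaflet headgroup point set.

    Undulation displaces each leaflet surface by
    ``amplitude * sin(2 pi x / wavelength)``; ``phase='anti'`` flips the
    sign on the lower leaflet so local thickness varies, while ``'in'``
    keeps thickness uniform. ``drift_per_frame`` linearly changes the
    leaflet separation over the trajectory (planted thinning/thickening).
    """

    lx: float = 10.0  # nm
    ly: float = 10.0
    separation: float = 4.0  # nm, mean headgroup z-distance between leaflets
    undulation_amplitude: float = 0.0
    undulation_wavelength: float = 5.0
    phase: str = "anti"  # 'anti' | 'in'
    noise_sigma: float = 0.0
    lipids_per_leaflet: int = 400
    n_frames: int = 1
    drift_per_frame: float = 0.0

    def validate(self) -> None:
        if self.separation <= 0:
            raise TrajectoryError("leaflet separation must be > 0")
        if self.noise_sigma < 0:
            raise TrajectoryError("noise sigma must be >= 0")
        if self.phase not in ("anti", "in"):
            raise TrajectoryError("phase must be 'anti' or 'in'")


def make_toy_complex(
    region_sizes: dict | None = None,
    peptide_sequence: str = "SLLMWITQC",
    seed: int = 0,
    spacing: float = 0.38,
):
    """Build a Calpha-only toy pMHC-TCR complex.

    One pseudo-atom per residue, regions spatially segregated (each region
    is a compact random coil around its own centre, peptide an extended
    strand between the groove and the TCR variable domains), peptide
    positions labelled P1..Pn. Returns (Topology, reference coords (N,3) nm).
    """
    sizes = dict(DEFAULT_REGION_SIZES if region_sizes is None else region_sizes)
    sizes.pop("peptide", None)
    required = {"groove", "Valpha", "Vbeta", "Calpha", "Cbeta"}
    missing = required - set(sizes)
    if missing:
        raise TrajectoryError(f"region_sizes lacks required regions: {sorted(missing)}")
    rng = np.random.default_rng(seed)

    centers = {
        "groove": np.array([0.0, 0.0, 0.0]),
        "peptide": np.array([0.0, 0.0, 1.5]),
        "Valpha": np.array([-2.5, 0.0, 4.5]),
        "Vbeta": np.array([2.5, 0.0, 4.5]),
        "Calpha": np.array([-2.5, 0.0, 8.0]),
        "Cbeta": np.array([2.5, 0.0, 8.0]),
    }

    names, elements, resindices, resids, resnames, chains = [], [], [], [], [], []
    region_map: dict[str, list] = {}
    coords = []
    resindex = 0

    def add_region(name: str, n_res: int, seqs=None):
        nonlocal resindex
        start = len(names)
        # compact self-avoiding-ish random coil confined near the centre
        pos = centers[name].copy()
        radius = spacing * max(2.0, 0.8 * n_res ** (1 / 3) * 1.8)
        for k in range(n_res):
            step = rng.normal(size=3)
            step *= spacing / np.linalg.norm(step)
            cand = pos + step
            # soft confinement: pull back toward the region centre
            off = cand - centers[name]
            dist = np.linalg.norm(off)
            if dist > radius:
                cand = centers[name] + off * (radius / dist)
            pos = cand
            coords.append(pos.copy())
            names.append("CA")
            elements.append("C")
            resindices.append(resindex)
            resids.append(k + 1)
            resnames.append(seqs[k] if seqs else "GLY")
            chains.append(_REGION_CHAINS[name])
            resindex += 1
        region_map[name] = list(range(start, len(names)))

    def add_peptide(sequence: str):
        nonlocal resindex
        start = len(names)
        n = len(sequence)
        for k, aa in enumerate(sequence):
            x = (k - (n - 1) / 2.0) * spacing
            coords.append(centers["peptide"] + np.array([x, 0.0, 0.0]))
            names.append("CA")
            elements.append("C")
            resindices.append(resindex)
            resids.append(k + 1)
            resnames.append(_AA3.get(aa, "UNK"))
            chains.append(_REGION_CHAINS["peptide"])
            resindex += 1
        region_map["peptide"] = list(range(start, len(names)))

    add_region("groove", sizes["groove"])
    add_peptide(peptide_sequence)
    for rname in ("Valpha", "Vbeta", "Calpha", "Cbeta"):
        add_region(rname, sizes[rname])

    top = Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resindices=np.array(resindices, dtype=int),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        chains=np.array(chains, dtype=object),
        region_map={k: np.array(v, dtype=int) for k, v in region_map.items()},
    )
    pep_res = top.residue_ids_of(top.region_map["peptide"])
    top.position_labels = {f"P{k + 1}": int(r) for k, r in enumerate(pep_res)}
    return top, np.asarray(coords)


def sample_ensemble(
    topology: Topology,
    reference: np.ndarray,
    mode_spec: ModeSpec,
    n_frames: int,
    seed: int = 0,
    dt_ns: float = 0.1,
) -> Ensemble:
    """Draw a Gaussian ensemble with population covariance
    ``sum_k a_k v_k v_k^T + epsilon I`` around the reference frame.

    The sample covariance converges to the prescribed one as the frame
    count grows; projecting the output onto mode k recovers a sample
    variance of a_k (the generator's core parameter-recovery property).
    """
    if n_frames < 2:
        raise TrajectoryError("n_frames must be >= 2")
    n_dof = 3 * topology.n_atoms
    mode_spec.validate(n_dof)
    rng = np.random.default_rng(seed)
    ref = np.asarray(reference, dtype=float).reshape(n_dof)
    frames = np.tile(ref, (n_frames, 1))
    for v, a in mode_spec.modes:
        z = rng.normal(scale=np.sqrt(a), size=n_frames)
        frames += np.outer(z, np.asarray(v, dtype=float))
    if mode_spec.epsilon > 0:
        frames += rng.normal(scale=np.sqrt(mode_spec.epsilon), size=frames.shape)
    return Ensemble(
        topology,
        frames.reshape(n_frames, topology.n_atoms, 3),
        times=dt_ns * np.arange(n_frames),
    )


def sample_correlated_regions(
    topology: Topology,
    reference: np.ndarray,
    region_correlations: dict,
    sigma: float = 0.1,
    jitter: float = 1e-4,
    n_frames: int = 1000,
    seed: int = 0,
    axis: int = 0,
    dt_ns: float = 0.1,
) -> Ensemble:
    """Plant pairwise region-region displacement correlations.

    ``region_correlations`` maps (regionA, regionB) -> rho in [-1, 1].
    Both regions of a pair receive a rigid per-frame displacement of
    standard deviation ``sigma`` nm along ``axis``, with the two scalar
    displacement series drawn from a bivariate normal of correlation rho;
    every atom additionally gets isotropic jitter so no atom is frozen.
    The planted atom-atom cross-correlation between the two regions is
    rho * sigma^2 / (sigma^2 + jitter^2) along the displaced axis.
    """
    rng = np.random.default_rng(seed)
    if n_frames < 2:
        raise TrajectoryError("n_frames must be >= 2")
    frames = np.tile(
        np.asarray(reference, dtype=float)[None, :, :], (n_frames, 1, 1)
    )
    for (ra, rb), rho in region_correlations.items():
        if not -1.0 <= rho <= 1.0:
            raise TrajectoryError(f"correlation target {rho} outside [-1, 1]")
        cov = sigma**2 * np.array([[1.0, rho], [rho, 1.0]])
        ab = rng.multivariate_normal([0.0, 0.0], cov, size=n_frames)
        ia = topology.atoms_in_region(ra)
        ib = topology.atoms_in_region(rb)
        frames[:, ia, axis] += ab[:, 0, None]
        frames[:, ib, axis] += ab[:, 1, None]
    if jitter > 0:
        frames += rng.normal(scale=jitter, size=frames.shape)
    return Ensemble(topology, frames, times=dt_ns * np.arange(n_frames))


def _leaflet_surface(x, y, spec: BilayerSpec, sign: float, sep: float) -> np.ndarray:
    z = sign * sep / 2.0
    und = spec.undulation_amplitude * np.sin(2 * np.pi * x / spec.undulation_wavelength)
    if spec.phase == "anti" and sign < 0:
        und = -und
    return z + und


def make_bilayer(spec: BilayerSpec, seed: int = 0):
    """Build a two-leaflet headgroup point set with prescribed thickness.

    Headgroups sit on a jittered lateral grid; each leaflet surface is
    displaced by the prescribed sinusoidal undulation (in phase or
    antiphase) plus Gaussian z-noise. Returns (Topology, Ensemble); the
    topology carries ``upper`` / ``lower`` / ``headgroups`` regions and
    per-leaflet chain labels U/L.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    n = spec.lipids_per_leaflet
    side = int(np.ceil(np.sqrt(n)))
    gx, gy = np.meshgrid(
        (np.arange(side) + 0.5) * spec.lx / side,
        (np.arange(side) + 0.5) * spec.ly / side,
    )
    lat = np.column_stack([gx.ravel()[:n], gy.ravel()[:n]])

    names, resindices, resids, chains = [], [], [], []
    for leaflet, chain in (("upper", "U"), ("lower", "L")):
        for k in range(n):
            names.append("P")
            resindices.append(len(resindices))
            resids.append(k + 1)
            chains.append(chain)
    n_tot = 2 * n
    top = Topology(
        names=np.array(names, dtype=object),
        elements=np.array(["P"] * n_tot, dtype=object),
        resindices=np.array(resindices, dtype=int),
        resids=np.array(resids, dtype=int),
        resnames=np.array(["POPC"] * n_tot, dtype=object),
        chains=np.array(chains, dtype=object),
        region_map={
            "upper": np.arange(n),
            "lower": np.arange(n, 2 * n),
            "headgroups": np.arange(2 * n),
        },
    )

    frames = np.empty((spec.n_frames, n_tot, 3))
    lz = spec.separation + 2 * spec.undulation_amplitude + 4.0
    boxes = np.tile([spec.lx, spec.ly, lz, 90.0, 90.0, 90.0], (spec.n_frames, 1))
    for t in range(spec.n_frames):
        sep = spec.separation + spec.drift_per_frame * t
        # small lateral jitter, same magnitude as z noise
        lat_t = lat + rng.normal(scale=spec.noise_sigma, size=lat.shape)
        zu = _leaflet_surface(lat_t[:, 0], lat_t[:, 1], spec, +1.0, sep)
        zl = _leaflet_surface(lat_t[:, 0], lat_t[:, 1], spec, -1.0, sep)
        if spec.noise_sigma > 0:
            zu = zu + rng.normal(scale=spec.noise_sigma, size=n)
            zl = zl + rng.normal(scale=spec.noise_sigma, size=n)
        frames[t, :n, :2] = lat_t % [spec.lx, spec.ly]
        frames[t, n:, :2] = lat_t % [spec.lx, spec.ly]
        frames[t, :n, 2] = zu
        frames[t, n:, 2] = zl
    return top, Ensemble(top, frames, box=boxes, times=0.1 * np.arange(spec.n_frames))


def make_hbond_trajectory(
    pairs,
    occupancy_targets,
    n_frames: int,
    seed: int = 0,
    bound_distance: float = 0.29,
    unbound_distance: float = 0.60,
):
    """Build a donor/acceptor pseudo-atom trajectory with planted occupancies.

    ``pairs`` is a list of ((partner_resname, partner_resid, partner_group),
    peptide_position) tuples, e.g. ``(("THR", 143, "groove"), "P9")``;
    ``occupancy_targets`` the matching list of per-pair occupancies in
    [0, 1]. Each pair occupies its own well-separated site; in a "bound"
    frame the acceptor sits at ``bound_distance`` nm from the donor, else
    at ``unbound_distance`` nm (outside the default criteria).

    Returns (Topology, Ensemble, planted) where ``planted`` maps
    (partner_label, position) -> target occupancy.
    """
    if len(pairs) != len(occupancy_targets):
        raise TrajectoryError("pairs and occupancy_targets must align")
    for occ in occupancy_targets:
        if not 0.0 <= occ <= 1.0:
            raise TrajectoryError("occupancies must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    group_chain = {"groove": "A", "TCRa": "D", "TCRb": "E"}
    names, resindices, resids, resnames, chains = [], [], [], [], []
    donor_ids, acceptor_ids = [], []
    positions = []
    resindex = 0
    pep_residue: dict[int, int] = {}  # peptide position -> shared residue index
    for k, ((resname, resid, group), pos_label) in enumerate(pairs):
        site = np.array([3.0 * k, 0.0, 0.0])
        donor_ids.append(len(names))
        names.append("O")
        resindices.append(resindex)
        resids.append(int(resid))
        resnames.append(str(resname).upper())
        chains.append(group_chain.get(group, "A"))
        resindex += 1
        pnum = int(str(pos_label).lstrip("P"))
        if pnum not in pep_residue:
            pep_residue[pnum] = resindex
            resindex += 1
        acceptor_ids.append(len(names))
        names.append("N")
        resindices.append(pep_residue[pnum])
        resids.append(pnum)
        resnames.append("PEP")
        chains.append("C")
        positions.append(site)

    n_atoms = len(names)
    region_map = {
        "donors": np.array(donor_ids, dtype=int),
        "acceptors": np.array(acceptor_ids, dtype=int),
        "peptide": np.array(acceptor_ids, dtype=int),
    }
    for group in sorted({g for (_, _, g), _ in pairs}):
        region_map[group] = np.array(
            [donor_ids[k] for k, ((_, _, g), _) in enumerate(pairs) if g == group],
            dtype=int,
        )
    top = Topology(
        names=np.array(names, dtype=object),
        elements=np.array([n[0] for n in names], dtype=object),
        resindices=np.array(resindices, dtype=int),
        resids=np.array(resids, dtype=int),
        resnames=np.array(resnames, dtype=object),
        chains=np.array(chains, dtype=object),
        region_map=region_map,
    )
    top.position_labels = {
        str(pos): int(top.resindices[acceptor_ids[k]])
        for k, (_, pos) in enumerate(pairs)
    }

    frames = np.zeros((n_frames, n_atoms, 3))
    for k, ((_, _, _), _) in enumerate(pairs):
        occ = occupancy_targets[k]
        bound = rng.random(n_frames) < occ if 0 < occ < 1 else np.full(
            n_frames, bool(occ)
        )
        d = np.where(bound, bound_distance, unbound_distance)
        frames[:, donor_ids[k], :] = positions[k]
        frames[:, acceptor_ids[k], :] = positions[k]
        frames[:, acceptor_ids[k], 2] += d
    planted = {
        (f"{rn.upper()}{ri}", pos): occ
        for ((rn, ri, _), pos), occ in zip(pairs, occupancy_targets)
    }
    ens = Ensemble(top, frames, times=0.1 * np.arange(n_frames))
    return top, ens, planted
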