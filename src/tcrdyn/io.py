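"""Readers and writers for standard structure/trajectory formats.

MDAnalysis does the heavy lifting (PDB, GRO, XTC, DCD, multi-model PDB);
this module converts everything into the package's nm-based
:class:`~tcrdyn.model.Topology` / :class:`~tcrdyn.model.Ensemble` types.
"""

from __future__ import annotations

import os
import warnings

import numpy as np

from .model import Ensemble, Topology, TrajectoryError

A_TO_NM = 0.1
PS_TO_NS = 1e-3

_STRUCTURE_FORMATS = {"PDB", "GRO"}
_TRAJECTORY_FORMATS = {"XTC", "DCD", "PDB"}  # PDB = multi-model


def _guess_format(path: str) -> str:
    return os.path.splitext(path)[1].lstrip(".").upper()


def _topology_from_universe(u) -> Topology:
    atoms = u.atoms
    n = len(atoms)

    def attr(name, default):
        if hasattr(atoms, name):
            return np.asarray(getattr(atoms, name), dtype=object)
        return np.full(n, default, dtype=object)

    names = attr("names", "X")
    elements = attr("elements", "")
    if (elements == "").all():
        # fall back to the first letter of the atom name (good enough for CA etc.)
        elements = np.array([str(nm)[:1] for nm in names], dtype=object)
    resnames = np.asarray(atoms.resnames, dtype=object)
    resids = np.asarray(atoms.resids, dtype=int)
    resindices = np.asarray(atoms.resindices, dtype=int)
    chains = attr("chainIDs", "")
    if (chains == "").all() and hasattr(atoms, "segids"):
        chains = np.asarray(atoms.segids, dtype=object)
    icodes = attr("icodes", "")
    return Topology(
        names=names,
        elements=elements,
        resindices=resindices,
        resids=resids,
        resnames=resnames,
        chains=chains,
        icodes=icodes,
    )


def _box_from_ts(ts) -> np.ndarray | None:
    dims = ts.dimensions
    if dims is None or not np.any(dims[:3]):
        return None
    out = np.array(dims, dtype=float)
    out[:3] *= A_TO_NM
    return out


def read_structure(path, fmt: str | None = None):
    """Read a PDB or GRO file into a Topology plus a single-frame Ensemble.

    Coordinates are converted from Angstrom to nm; atom order, residue
    numbering (including insertion codes) and chain ids are preserved.
    """
    import MDAnalysis as mda

    fmt = (fmt or _guess_format(path)).upper()
    if fmt not in _STRUCTURE_FORMATS:
        raise TrajectoryError(f"unsupported structure format {fmt!r} (use PDB or GRO)")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(path, format=fmt)
    except (ValueError, OSError) as exc:
        raise TrajectoryError(f"cannot parse {path} as {fmt}: {exc}") from exc
    top = _topology_from_universe(u)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ts = u.trajectory[0]
        coords = u.atoms.positions[None, :, :] * A_TO_NM
        box = _box_from_ts(ts)
    ens = Ensemble(top, coords, box=None if box is None else box[None, :], times=None)
    return top, ens


def read_trajectory(
    topology: Topology,
    path,
    fmt: str | None = None,
    dt_ns: float | None = None,
    t0_ns: float = 0.0,
) -> Ensemble:
    """Read an XTC/DCD/multi-model-PDB trajectory against an existing topology.

    Timestamps come from the file when it carries them; otherwise they are
    synthesized as ``t0_ns + k * dt_ns`` (the frame-saving stride is
    metadata the user must supply for formats that lack it).
    """
    import MDAnalysis as mda

    fmt = (fmt or _guess_format(path)).upper()
    if fmt not in _TRAJECTORY_FORMATS:
        raise TrajectoryError(f"unsupported trajectory format {fmt!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt == "PDB":
                u = mda.Universe(path, format="PDB")
            else:
                u = mda.Universe.empty(topology.n_atoms, trajectory=True)
                u.load_new(path, format=fmt)
    except ValueError as exc:
        raise TrajectoryError(
            f"trajectory {path} does not match the topology "
            f"({topology.n_atoms} atoms): {exc}"
        ) from exc
    if len(u.atoms) != topology.n_atoms:
        raise TrajectoryError(
            f"trajectory {path} has {len(u.atoms)} atoms but the topology has "
            f"{topology.n_atoms}"
        )
    coords, boxes, times = [], [], []
    have_box = True
    file_times = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # e.g. "Reader has no dt information"
        for ts in u.trajectory:
            coords.append(u.atoms.positions * A_TO_NM)
            b = _box_from_ts(ts)
            if b is None:
                have_box = False
            else:
                boxes.append(b)
            t = getattr(ts, "time", None)
            if t is None:
                file_times = False
            else:
                times.append(float(t) * PS_TO_NS)
    coords = np.asarray(coords)
    T = len(coords)
    if dt_ns is not None:
        tarr = t0_ns + dt_ns * np.arange(T)
    elif file_times and len(times) == T and (T < 2 or np.all(np.diff(times) > 0)):
        tarr = np.asarray(times)
    else:
        tarr = None
    return Ensemble(
        topology,
        coords,
        box=np.asarray(boxes) if have_box and len(boxes) == T else None,
        times=tarr,
    )


def write_structure(topology: Topology, coords_nm: np.ndarray, path) -> None:
    """Write a single frame as PDB (nm converted back to Angstrom)."""
    u = _universe_from_topology(topology, coords_nm[None, :, :])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(ensemble: Ensemble, path, fmt: str | None = None) -> None:
    """Write an Ensemble as XTC/DCD or multi-model PDB."""
    import MDAnalysis as mda

    fmt = (fmt or _guess_format(path)).upper()
    u = _universe_from_topology(ensemble.topology, ensemble.coords, ensemble.box)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=ensemble.n_atoms, format=fmt, multiframe=True) as w:
            for ts in u.trajectory:
                if ensemble.times is not None:
                    ts.time = ensemble.times[ts.frame] / PS_TO_NS
                w.write(u.atoms)


def _universe_from_topology(topology: Topology, coords_nm: np.ndarray, box=None):
    import MDAnalysis as mda

    n = topology.n_atoms
    nres = int(topology.resindices.max()) + 1 if n else 0
    u = mda.Universe.empty(
        n,
        n_residues=nres,
        atom_resindex=topology.resindices,
        residue_segindex=np.zeros(nres, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in topology.names])
    u.add_TopologyAttr("elements", [str(x) for x in topology.elements])
    first_atom = [int(np.argmax(topology.resindices == r)) for r in range(nres)]
    u.add_TopologyAttr("resnames", [str(topology.resnames[i]) for i in first_atom])
    u.add_TopologyAttr("resids", [int(topology.resids[i]) for i in first_atom])
    u.add_TopologyAttr("chainIDs", [str(x) for x in topology.chains])
    xyz = np.asarray(coords_nm) / A_TO_NM
    dims = None
    if box is not None:
        dims = np.asarray(box, dtype=float).copy()
        dims[:, :3] /= A_TO_NM
    u.load_new(xyz, format="memory", dimensions=dims, order="fac")
    return u
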