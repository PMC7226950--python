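"""Core data model for structures, ensembles and named region selections.

The internal length unit is the nanometre throughout (file readers convert
from Angstrom on the fly); residue numbering follows the 1-based author
numbering of the input files, while atom indices are internal and 0-based.

Regions (``groove``, ``peptide``, ``Valpha``, ``Vbeta``, ``Calpha``,
``Cbeta`` ...) are named atom selections declared in a structured config
rather than guessed from chains, because the constructs under study differ
in sequence and chain layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "Topology",
    "Ensemble",
    "Selection",
    "TrajectoryError",
    "load_region_config",
    "apply_region_config",
    "trim_equilibration",
]


class TrajectoryError(ValueError):
    """Raised for malformed structures, ensembles or selections."""


@dataclass
class Topology:
    """Atoms, residues and named region selections of one molecular system.

    All per-atom arrays have length ``n_atoms``. ``region_map`` maps a
    region name to an ordered array of atom ids; ``position_labels`` maps
    peptide position labels (``P1``..``Pn``) to residue indices
    (internal, 0-based) in peptide sequence order.
    """

    names: np.ndarray
    elements: np.ndarray
    resindices: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    icodes: np.ndarray | None = None
    charges: np.ndarray | None = None
    lj_sigma: np.ndarray | None = None  # nm
    lj_epsilon: np.ndarray | None = None  # kJ/mol
    region_map: dict[str, np.ndarray] = field(default_factory=dict)
    position_labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "resindices", "resids", "resnames", "chains"):
            if len(getattr(self, attr)) != n:
                raise TrajectoryError(f"per-atom array {attr!r} has wrong length")
        if self.icodes is None:
            self.icodes = np.full(n, "", dtype=object)
        self.validate_regions()

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.resindices))

    def validate_regions(self) -> None:
        for name, ids in self.region_map.items():
            ids = np.asarray(ids, dtype=int)
            if ids.size and (ids.min() < 0 or ids.max() >= self.n_atoms):
                raise TrajectoryError(f"region {name!r} references unknown atoms")
            if len(np.unique(ids)) != len(ids):
                raise TrajectoryError(f"region {name!r} lists an atom twice")
            self.region_map[name] = ids

    def atoms_in_region(self, name: str) -> np.ndarray:
        if name not in self.region_map:
            raise TrajectoryError(
                f"unknown region {name!r}; declared regions: {sorted(self.region_map)}"
            )
        return self.region_map[name]

    def residue_ids_of(self, atom_ids: np.ndarray) -> np.ndarray:
        """Internal residue indices of the given atoms, order-preserving, deduplicated."""
        seen: dict[int, None] = {}
        for r in self.resindices[np.asarray(atom_ids, dtype=int)]:
            seen.setdefault(int(r))
        return np.array(list(seen), dtype=int)

    def residue_label(self, resindex: int) -> str:
        mask = self.resindices == resindex
        if not mask.any():
            raise TrajectoryError(f"unknown residue index {resindex}")
        i = int(np.argmax(mask))
        icode = self.icodes[i] if self.icodes is not None else ""
        return f"{self.resnames[i]}{self.resids[i]}{icode}:{self.chains[i]}"


@dataclass(frozen=True)
class Selection:
    """Deterministic, order-preserving atom selection.

    Compose with ``|`` (union, left-to-right order) and ``&``
    (intersection, order of the left operand).
    """

    ids: tuple[int, ...]
    expression: str = ""

    @staticmethod
    def from_ids(ids, expression: str = "ids") -> "Selection":
        return Selection(tuple(int(i) for i in ids), expression)

    @staticmethod
    def region(topology: Topology, name: str) -> "Selection":
        return Selection(tuple(int(i) for i in topology.atoms_in_region(name)), name)

    @staticmethod
    def chain_resids(topology: Topology, chain: str, ranges) -> "Selection":
        """Atoms of ``chain`` whose author resid falls in any (lo, hi) range."""
        mask = np.zeros(topology.n_atoms, dtype=bool)
        in_chain = topology.chains == chain
        for lo, hi in ranges:
            mask |= in_chain & (topology.resids >= lo) & (topology.resids <= hi)
        ids = np.flatnonzero(mask)
        return Selection(tuple(int(i) for i in ids), f"chain {chain} resid {ranges}")

    @staticmethod
    def atom_names(topology: Topology, names) -> "Selection":
        names = set(names)
        ids = [i for i, n in enumerate(topology.names) if n in names]
        return Selection(tuple(ids), f"name {sorted(names)}")

    def __or__(self, other: "Selection") -> "Selection":
        have = set(self.ids)
        ids = list(self.ids) + [i for i in other.ids if i not in have]
        return Selection(tuple(ids), f"({self.expression}) or ({other.expression})")

    def __and__(self, other: "Selection") -> "Selection":
        keep = set(other.ids)
        return Selection(
            tuple(i for i in self.ids if i in keep),
            f"({self.expression}) and ({other.expression})",
        )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.ids, dtype=int)


def as_indices(topology: Topology, selection) -> np.ndarray:
    """Coerce a Selection, region name or index array to an atom-id array."""
    if selection is None:
        return np.arange(topology.n_atoms)
    if isinstance(selection, Selection):
        return selection.indices
    if isinstance(selection, str):
        return topology.atoms_in_region(selection)
    return np.asarray(selection, dtype=int)


@dataclass
class Ensemble:
    """An ordered set of frames (T x N x 3 coordinates, nm) over a Topology.

    ``box`` holds per-frame unit-cell dimensions ``[lx, ly, lz, alpha,
    beta, gamma]`` (nm, degrees) when periodic information exists;
    ``times`` holds per-frame timestamps in ns.
    """

    topology: Topology
    coords: np.ndarray
    box: np.ndarray | None = None
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (T, N, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.n_frames:
                raise TrajectoryError("times length must equal frame count")
            if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
                raise TrajectoryError("timestamps must be strictly increasing")
        if self.box is not None:
            self.box = np.atleast_2d(np.asarray(self.box, dtype=float))
            if self.box.shape != (self.n_frames, 6):
                raise TrajectoryError("box must have shape (T, 6)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def subset_frames(self, frame_idx) -> "Ensemble":
        frame_idx = np.asarray(frame_idx, dtype=int)
        return replace(
            self,
            coords=self.coords[frame_idx],
            box=None if self.box is None else self.box[frame_idx],
            times=None if self.times is None else self.times[frame_idx],
        )


def trim_equilibration(ensemble: Ensemble, t_start: float) -> Ensemble:
    """Drop the equilibration head: keep only frames with time >= ``t_start`` ns.

    Trajectories of large membrane-embedded complexes take tens of ns to
    reach an RMSD plateau; the study workflow discards the first 50 ns
    before any analysis. An empty result is legal but warned about.
    """
    if t_start < 0:
        raise TrajectoryError("t_start must be >= 0")
    if t_start == 0:
        return ensemble
    if ensemble.times is None:
        raise TrajectoryError("ensemble has no timestamps; cannot trim by time")
    keep = np.flatnonzero(ensemble.times >= t_start)
    if keep.size == 0:
        warnings.warn(
            f"trim_equilibration: no frames at or after t={t_start} ns", stacklevel=2
        )
    return ensemble.subset_frames(keep)


def load_region_config(path) -> dict:
    """Load a region-definition config (YAML).

    Expected layout::

        regions:
          groove:  {chain: A, resids: [[1, 175]]}
          peptide: {chain: C, resids: [[1, 9]], peptide_positions: true}
          Valpha:  {chain: D, resids: [[1, 110]]}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "regions" not in cfg:
        raise TrajectoryError(f"region config {path} lacks a 'regions' block")
    return cfg["regions"]


def apply_region_config(topology: Topology, regions: dict) -> Topology:
    """Resolve a region config against a topology, filling ``region_map``.

    A region marked ``peptide_positions: true`` additionally labels its
    residues P1..Pn in author-resid order.
    """
    for name, spec in regions.items():
        sel = Selection.chain_resids(topology, str(spec["chain"]), spec["resids"])
        if len(sel) == 0:
            raise TrajectoryError(f"region {name!r} resolves to no atoms")
        topology.region_map[name] = sel.indices
        if spec.get("peptide_positions"):
            res = topology.residue_ids_of(sel.indices)
            order = np.argsort([topology.resids[topology.resindices == r][0] for r in res])
            topology.position_labels = {
                f"P{k + 1}": int(res[j]) for k, j in enumerate(order)
            }
    topology.validate_regions()
    return topology
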