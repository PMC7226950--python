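"""Residue-contact networks and per-residue topological descriptors.

Each residue is a node; two nodes are joined when their alpha-carbon
distance is strictly below a cutoff (default 0.6 nm). Degree and
closeness centrality are accumulated over a sample of frames (about 100
per trajectory in the original workflow), giving per-residue metric
distributions suitable for boxplots.

Closeness uses the Wasserman-Faust component-size scaling so values stay
comparable across frames even when the contact graph disconnects.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .model import Ensemble, Topology, TrajectoryError, as_indices

__all__ = [
    "ContactGraph",
    "build_contact_graph",
    "node_degree",
    "closeness_centrality",
    "metric_distributions",
    "DEFAULT_CUTOFF_NM",
]

DEFAULT_CUTOFF_NM = 0.6  # the 6 Angstrom contact threshold


@dataclass
class ContactGraph:
    graph: nx.Graph
    cutoff: float
    frame_id: int
    residues: np.ndarray  # node order (internal residue indices)


def _ca_per_residue(topology: Topology, idx: np.ndarray):
    """Map residue -> CA atom id within a selection; error when missing."""
    names = topology.names[idx]
    res = topology.resindices[idx]
    out: dict[int, int] = {}
    for atom, name, r in zip(idx, names, res):
        if name == "CA" and int(r) not in out:
            out[int(r)] = int(atom)
    all_res = {int(r) for r in res}
    missing = all_res - set(out)
    if missing:
        # Calpha-only pseudo-atom fixtures name everything CA; a residue
        # with no CA at all is a real input error
        raise TrajectoryError(
            f"residues without an alpha carbon: {sorted(missing)[:5]}"
        )
    return out


def build_contact_graph(
    ensemble_or_frame,
    frame: int = 0,
    selection=None,
    cutoff: float = DEFAULT_CUTOFF_NM,
) -> ContactGraph:
    """Residue-contact graph of one frame (edge iff CA-CA distance < cutoff)."""
    if isinstance(ensemble_or_frame, Ensemble):
        ens = ensemble_or_frame
        top = ens.topology
        coords = ens.coords[frame]
    else:
        raise TrajectoryError("pass an Ensemble (with frame index)")
    idx = as_indices(top, selection)
    ca = _ca_per_residue(top, idx)
    residues = np.array(sorted(ca), dtype=int)
    pts = coords[[ca[int(r)] for r in residues]]
    dist = squareform(pdist(pts))
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in residues)
    ii, jj = np.nonzero(np.triu(dist < cutoff, k=1))
    g.add_edges_from((int(residues[i]), int(residues[j])) for i, j in zip(ii, jj))
    return ContactGraph(graph=g, cutoff=cutoff, frame_id=frame, residues=residues)


def node_degree(cg: ContactGraph) -> dict:
    """Number of contacting residues per node."""
    return {int(n): int(d) for n, d in cg.graph.degree()}


def closeness_centrality(cg: ContactGraph) -> dict:
    """Component-scaled closeness: ((n_c-1)/(n-1)) * (n_c-1)/sum d(v,u).

    Isolated nodes get 0. networkx's ``wf_improved`` closeness implements
    exactly this scaling.
    """
    return {int(n): float(v) for n, v in nx.closeness_centrality(cg.graph, wf_improved=True).items()}


def metric_distributions(
    ensemble: Ensemble,
    selection=None,
    sample_n: int = 100,
    cutoff: float = DEFAULT_CUTOFF_NM,
    sampling: str = "even",
    seed: int | None = None,
) -> pd.DataFrame:
    """Degree and closeness distributions over sampled frames.

    Frames are sampled evenly spaced (deterministic default) or uniformly
    at random with a seed. Returns a long-format table (residue, frame,
    metric, value).
    """
    T = ensemble.n_frames
    if sample_n > T:
        raise TrajectoryError(f"sample_n={sample_n} exceeds frame count {T}")
    if sampling == "even":
        frames = np.unique(np.linspace(0, T - 1, sample_n).round().astype(int))
    elif sampling == "random":
        rng = np.random.default_rng(seed)
        frames = np.sort(rng.choice(T, size=sample_n, replace=False))
    else:
        raise TrajectoryError("sampling must be 'even' or 'random'")
    rows = []
    for f in frames:
        cg = build_contact_graph(ensemble, frame=int(f), selection=selection, cutoff=cutoff)
        deg = node_degree(cg)
        clo = closeness_centrality(cg)
        for r in cg.residues:
            rows.append((int(r), int(f), "degree", float(deg[int(r)])))
            rows.append((int(r), int(f), "closeness", clo[int(r)]))
    return pd.DataFrame(rows, columns=["residue", "frame", "metric", "value"])
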