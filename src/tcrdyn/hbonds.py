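"""Hydrogen-bond detection, occupancy tables and peptide anchor analysis.

A bond is reported when the donor-acceptor distance is at most ``d_cut``
(default 0.35 nm) and, when explicit hydrogens exist, the
hydrogen-donor-acceptor angle is at most ``angle_cut`` (default 30
degrees). Calpha-only or heavy-atom-only systems fall back to the
distance criterion alone (flagged in the output).

Occupancy is the fraction of analysed frames in which a
(partner residue, peptide position) pair is bonded. Anchor analysis flags
the terminal peptide positions (P1-P2 and P(n-1)-Pn) whose persistent
groove contacts fix the ligand into the MHC pockets, and the central
positions (around P4-P5) that contact the TCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Ensemble, Topology, TrajectoryError, as_indices

__all__ = [
    "HBondCriteria",
    "HBond",
    "detect_hbonds",
    "occupancy_table",
    "presence_table",
    "anchor_analysis",
]


@dataclass(frozen=True)
class HBondCriteria:
    d_cut: float = 0.35  # nm, donor-acceptor distance
    angle_cut: float = 30.0  # degrees, hydrogen-donor-acceptor angle


@dataclass(frozen=True)
class HBond:
    donor: int
    acceptor: int
    donor_residue: int
    acceptor_residue: int
    frame: int
    hydrogen: int | None = None


def _pair_distances(coords, ids_a, ids_b):
    return np.linalg.norm(
        coords[ids_a][:, None, :] - coords[ids_b][None, :, :], axis=2
    )


def detect_hbonds(
    ensemble: Ensemble,
    frame: int,
    donor_selection,
    acceptor_selection,
    criteria: HBondCriteria = HBondCriteria(),
    hydrogen_map: dict | None = None,
) -> list:
    """Hydrogen bonds in one frame between donor and acceptor selections.

    ``hydrogen_map`` maps donor atom id -> attached hydrogen atom id; when
    absent (heavy-atom fixtures) only the distance criterion applies.
    """
    top = ensemble.topology
    don = as_indices(top, donor_selection)
    acc = as_indices(top, acceptor_selection)
    if len(don) == 0 or len(acc) == 0:
        raise TrajectoryError("empty donor or acceptor selection")
    coords = ensemble.coords[frame]
    dist = _pair_distances(coords, don, acc)
    out = []
    for i, j in zip(*np.nonzero(dist <= criteria.d_cut)):
        d_id, a_id = int(don[i]), int(acc[j])
        if d_id == a_id:
            continue
        h_id = None if hydrogen_map is None else hydrogen_map.get(d_id)
        if h_id is not None:
            hd = coords[h_id] - coords[d_id]
            da = coords[a_id] - coords[d_id]
            cosang = np.dot(hd, da) / (np.linalg.norm(hd) * np.linalg.norm(da))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle > criteria.angle_cut:
                continue
        out.append(
            HBond(
                donor=d_id,
                acceptor=a_id,
                donor_residue=int(top.resindices[d_id]),
                acceptor_residue=int(top.resindices[a_id]),
                frame=frame,
                hydrogen=h_id,
            )
        )
    return out


def _partner_group(top: Topology, atom_id: int, partner_groups: dict) -> str:
    for name, ids in partner_groups.items():
        if atom_id in ids:
            return name
    return "other"


def occupancy_table(
    ensemble: Ensemble,
    peptide_selection="peptide",
    partner_selections: dict | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    hydrogen_map: dict | None = None,
) -> pd.DataFrame:
    """Per-(partner residue, peptide position) H-bond occupancy.

    ``partner_selections`` maps a partner group label (``groove``,
    ``TCRa``, ``TCRb`` ...) to a selection; peptide residues must carry
    position labels P1..Pn on the topology. Occupancy = bonded frames /
    total frames. Pairs never detected are absent from the table.
    """
    top = ensemble.topology
    if not top.position_labels:
        raise TrajectoryError("topology has no peptide position labels")
    if partner_selections is None:
        partner_selections = {
            name: top.region_map[name]
            for name in ("groove", "TCRa", "TCRb")
            if name in top.region_map
        }
    res_to_pos = {r: p for p, r in top.position_labels.items()}
    pep = as_indices(top, peptide_selection)
    counts: dict[tuple, int] = {}
    groups = {
        name: set(as_indices(top, sel).tolist()) for name, sel in partner_selections.items()
    }
    T = ensemble.n_frames
    for t in range(T):
        seen_this_frame: set = set()
        for gname, sel in partner_selections.items():
            bonds = detect_hbonds(
                ensemble, t, sel, pep, criteria=criteria, hydrogen_map=hydrogen_map
            )
            for b in bonds:
                pos = res_to_pos.get(b.acceptor_residue)
                if pos is None:
                    continue
                key = (top.residue_label(b.donor_residue), pos, gname)
                if key not in seen_this_frame:
                    seen_this_frame.add(key)
                    counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "partner_residue": k[0],
            "peptide_position": k[1],
            "partner_group": k[2],
            "occupancy": n / T,
        }
        for k, n in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["partner_residue", "peptide_position", "partner_group", "occupancy"]
    )


def presence_table(table: pd.DataFrame, min_occupancy: float = 0.1) -> pd.DataFrame:
    """Partner-residue x peptide-position presence matrix.

    Mirrors a presence-style H-bond table: a cell holds the peptide
    position when the pair's occupancy reaches ``min_occupancy``.
    """
    keep = table[table["occupancy"] >= min_occupancy]
    if keep.empty:
        return pd.DataFrame()
    return keep.pivot_table(
        index="partner_residue",
        columns="peptide_position",
        values="occupancy",
        aggfunc="max",
    )


@dataclass
class AnchorReport:
    anchored_positions: list = field(default_factory=list)
    n_terminal_anchor: bool = False
    c_terminal_anchor: bool = False
    central_tcr_contact: bool = False
    central_positions: list = field(default_factory=list)


def anchor_analysis(
    table: pd.DataFrame,
    min_occupancy: float = 0.5,
    n_positions: int | None = None,
) -> AnchorReport:
    """Flag peptide anchor sites from an occupancy table.

    The terminal anchors are groove contacts at P1-P2 and P(n-1)-Pn (the
    conserved pockets that fix the two ends of the ligand); central TCR
    contacts around P4-P5 are reported separately. An empty table gives an
    explicit empty report.
    """
    report = AnchorReport()
    if table.empty:
        return report
    pos_num = table["peptide_position"].str.lstrip("P").astype(int)
    if n_positions is None:
        n_positions = int(pos_num.max())
    groove = table[(table["partner_group"] == "groove") & (table["occupancy"] >= min_occupancy)]
    anchored = sorted(
        groove["peptide_position"].unique(), key=lambda p: int(p.lstrip("P"))
    )
    report.anchored_positions = list(anchored)
    nums = {int(p.lstrip("P")) for p in anchored}
    report.n_terminal_anchor = bool(nums & {1, 2})
    report.c_terminal_anchor = bool(nums & {n_positions - 1, n_positions})
    tcr = table[
        table["partner_group"].isin(["TCRa", "TCRb"]) & (table["occupancy"] >= min_occupancy)
    ]
    central = {int(p.lstrip("P")) for p in tcr["peptide_position"].unique()}
    mid = {n_positions // 2, (n_positions + 1) // 2, n_positions // 2 + 1}
    report.central_positions = sorted(f"P{k}" for k in central)
    report.central_tcr_contact = bool(central & mid)
    return report
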