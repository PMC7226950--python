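"""Grid-based bilayer thickness and inter-selection minimum distances.

Thickness follows the GridMAT approach: the lateral plane is divided into
a rectangular grid (default 100 x 100 cells); each cell's thickness is
the z of the laterally nearest upper-leaflet headgroup minus the z of the
nearest lower-leaflet headgroup. Leaflets are assigned by the sign of z
relative to the membrane midplane (mean headgroup z). Minimum distances
between selections are periodic-image aware when a box is present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import Ensemble, TrajectoryError, as_indices

__all__ = [
    "ThicknessMap",
    "assign_leaflets",
    "thickness_map",
    "thickness_comparison",
    "bilayer_distance_series",
]


@dataclass
class ThicknessMap:
    values: np.ndarray  # (n_x, n_y) nm
    occupied: np.ndarray  # bool mask; cells flagged False carry no lipid support
    x_edges: np.ndarray
    y_edges: np.ndarray
    frame_id: int

    @property
    def mean(self) -> float:
        return float(self.values[self.occupied].mean())


def assign_leaflets(ensemble: Ensemble, frame: int = 0, headgroup_selection="headgroups"):
    """Partition headgroups into upper/lower leaflets by midplane sign.

    Returns (upper atom ids, lower atom ids). A one-sided z distribution
    (all headgroups on one side of their mean) is a degenerate bilayer.
    """
    idx = as_indices(ensemble.topology, headgroup_selection)
    if len(idx) < 2:
        raise TrajectoryError("need at least 2 headgroups")
    z = ensemble.coords[frame, idx, 2]
    mid = z.mean()
    upper = idx[z > mid]
    lower = idx[z < mid]
    if len(upper) == 0 or len(lower) == 0:
        raise TrajectoryError("degenerate bilayer: all headgroups on one side of the midplane")
    return upper, lower


def thickness_map(
    ensemble: Ensemble,
    frame: int = 0,
    leaflets=None,
    n_x: int = 100,
    n_y: int = 100,
    headgroup_selection="headgroups",
    max_lateral: float | None = None,
) -> ThicknessMap:
    """Per-cell bilayer thickness on an n_x x n_y lateral grid.

    The grid spans the box's lateral dimensions when a box is present,
    else the lateral bounding box of the headgroups. ``max_lateral``
    optionally flags cells whose nearest headgroup (either leaflet) is
    farther than that lateral distance, instead of zero-filling them.
    """
    if leaflets is None:
        leaflets = assign_leaflets(ensemble, frame, headgroup_selection)
    upper, lower = leaflets
    coords = ensemble.coords[frame]
    if ensemble.box is not None:
        lx, ly = ensemble.box[frame, 0], ensemble.box[frame, 1]
        x_edges = np.linspace(0.0, lx, n_x + 1)
        y_edges = np.linspace(0.0, ly, n_y + 1)
    else:
        allxy = coords[np.concatenate([upper, lower])][:, :2]
        x_edges = np.linspace(allxy[:, 0].min(), allxy[:, 0].max(), n_x + 1)
        y_edges = np.linspace(allxy[:, 1].min(), allxy[:, 1].max(), n_y + 1)
    cx = 0.5 * (x_edges[:-1] + x_edges[1:])
    cy = 0.5 * (y_edges[:-1] + y_edges[1:])
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    tu = cKDTree(coords[upper][:, :2])
    tl = cKDTree(coords[lower][:, :2])
    du, iu = tu.query(centers)
    dl, il = tl.query(centers)
    thick = coords[upper][iu, 2] - coords[lower][il, 2]
    occupied = np.ones(len(centers), dtype=bool)
    if max_lateral is not None:
        occupied = (du <= max_lateral) & (dl <= max_lateral)
    return ThicknessMap(
        values=thick.reshape(n_x, n_y),
        occupied=occupied.reshape(n_x, n_y),
        x_edges=x_edges,
        y_edges=y_edges,
        frame_id=frame,
    )


def thickness_comparison(
    ensemble: Ensemble, n_x: int = 100, n_y: int = 100, headgroup_selection="headgroups"
) -> dict:
    """Mean thickness of the two trajectory halves and their difference.

    Each frame contributes its thickness-map grand mean; the two halves of
    the trajectory are then summarized by mean and standard deviation. A
    single-frame half is flagged low-confidence.
    """
    T = ensemble.n_frames
    if T < 2:
        raise TrajectoryError("need at least 2 frames to compare halves")
    means = np.array(
        [
            thickness_map(
                ensemble, frame=t, n_x=n_x, n_y=n_y, headgroup_selection=headgroup_selection
            ).mean
            for t in range(T)
        ]
    )
    half = T // 2
    first, second = means[:half], means[half:]
    return {
        "first_half_mean": float(first.mean()),
        "first_half_std": float(first.std(ddof=0)),
        "second_half_mean": float(second.mean()),
        "second_half_std": float(second.std(ddof=0)),
        "difference": float(second.mean() - first.mean()),
        "low_confidence": bool(len(first) < 2 or len(second) < 2),
    }


def _min_image_diff(diff: np.ndarray, box_lengths: np.ndarray) -> np.ndarray:
    return diff - box_lengths * np.round(diff / box_lengths)


def bilayer_distance_series(
    ensemble: Ensemble, selection_a, selection_b
) -> pd.DataFrame:
    """Per-frame minimum distance between two selections (nm).

    With a periodic box, the minimum-image convention applies (orthorhombic
    boxes). Typical use: headgroup selections of two stacked bilayers.
    """
    top = ensemble.topology
    ia = as_indices(top, selection_a)
    ib = as_indices(top, selection_b)
    if len(ia) == 0 or len(ib) == 0:
        raise TrajectoryError("empty selection")
    out = []
    for t in range(ensemble.n_frames):
        pa = ensemble.coords[t, ia, :]
        pb = ensemble.coords[t, ib, :]
        diff = pa[:, None, :] - pb[None, :, :]
        if ensemble.box is not None:
            diff = _min_image_diff(diff, ensemble.box[t, :3])
        d = np.sqrt(np.sum(diff**2, axis=2))
        out.append(float(d.min()))
    times = (
        ensemble.times if ensemble.times is not None else np.arange(ensemble.n_frames)
    )
    return pd.DataFrame({"time_ns": times, "min_distance_nm": out})
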