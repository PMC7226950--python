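"""Rigid-body superposition, RMSD time series and RMSF profiles.

RMSD(t) = sqrt((1/N) sum_i |r_i(t) - r_i^0|^2) over a selected atom group
against a reference structure (by default the first frame); RMSF_i =
sqrt((1/T) sum_t |r_i(t) - ref_i|^2) with the reference either the initial
structure (default, the literal definition) or the time average.
Frames are least-squares superposed onto the reference over the fit
selection before measuring, matching the conventional GROMACS workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Ensemble, TrajectoryError, as_indices

__all__ = [
    "RigidTransform",
    "RmsdSeries",
    "RmsfProfile",
    "superpose",
    "rmsd_series",
    "rmsf_profile",
    "rmsf_by_residue",
]


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ (x - mobile_centroid) + ref_centroid, with det(R) = +1."""

    rotation: np.ndarray
    mobile_centroid: np.ndarray
    ref_centroid: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.mobile_centroid) @ self.rotation.T + self.ref_centroid


@dataclass
class RmsdSeries:
    values: np.ndarray  # nm, one per frame
    times: np.ndarray | None
    reference: str
    selection: str
    fitted: bool

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise TrajectoryError("RMSD values must be >= 0")


@dataclass
class RmsfProfile:
    values: np.ndarray  # nm, one per selected atom
    atom_ids: np.ndarray
    reference_mode: str
    selection: str

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise TrajectoryError("RMSF values must be >= 0")


def superpose(mobile: np.ndarray, reference: np.ndarray, selection=None):
    """Least-squares (Kabsch) fit of ``mobile`` onto ``reference``.

    The fit is computed over ``selection`` (atom indices; all atoms when
    None) and applied to the full mobile frame. Returns
    (RigidTransform, transformed mobile coords). The rotation is proper
    (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = np.arange(len(mobile)) if selection is None else np.asarray(selection, int)
    if len(idx) < 3:
        raise TrajectoryError("superposition needs >= 3 atoms")
    a = mobile[idx]
    b = reference[idx]
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinearity check: rank of the centred point cloud
    if np.linalg.matrix_rank(a0, tol=1e-10) < 2 or np.linalg.matrix_rank(b0, tol=1e-10) < 2:
        raise TrajectoryError("degenerate (collinear) selection for superposition")
    h = a0.T @ b0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    tr = RigidTransform(rotation=rot, mobile_centroid=ca, ref_centroid=cb)
    return tr, tr.apply(mobile)


def _fit_frames(coords, reference, fit_idx):
    out = np.empty_like(coords)
    for t in range(len(coords)):
        _, out[t] = superpose(coords[t], reference, fit_idx)
    return out


def rmsd_series(
    ensemble: Ensemble,
    reference=0,
    selection=None,
    fit: bool = True,
    fit_selection=None,
) -> RmsdSeries:
    """Per-frame RMSD against a reference frame.

    ``reference`` is a frame index or an explicit (N, 3) coordinate array;
    ``selection`` names the measured atom group (region name, Selection or
    index array); ``fit_selection`` defaults to the measured group.
    """
    idx = as_indices(ensemble.topology, selection)
    if len(idx) == 0:
        raise TrajectoryError("empty selection")
    ref = (
        ensemble.coords[int(reference)]
        if np.isscalar(reference)
        else np.asarray(reference, dtype=float)
    )
    coords = ensemble.coords
    if fit:
        fit_idx = idx if fit_selection is None else as_indices(ensemble.topology, fit_selection)
        coords = _fit_frames(coords, ref, fit_idx)
    diff = coords[:, idx, :] - ref[idx]
    vals = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    return RmsdSeries(
        values=vals,
        times=ensemble.times,
        reference="frame0" if np.isscalar(reference) else "external",
        selection=str(selection),
        fitted=fit,
    )


def rmsf_profile(
    ensemble: Ensemble,
    reference=0,
    selection=None,
    reference_mode: str = "initial",
    fit: bool = True,
) -> RmsfProfile:
    """Per-atom RMSF over the trajectory.

    ``reference_mode='initial'`` measures deviation from the initial
    (reference) structure — the literal fluctuation definition used here;
    ``'mean'`` measures about the time average, which is never larger.
    """
    if ensemble.n_frames < 2:
        raise TrajectoryError("RMSF needs at least 2 frames")
    if reference_mode not in ("initial", "mean"):
        raise TrajectoryError("reference_mode must be 'initial' or 'mean'")
    idx = as_indices(ensemble.topology, selection)
    if len(idx) == 0:
        raise TrajectoryError("empty selection")
    ref = (
        ensemble.coords[int(reference)]
        if np.isscalar(reference)
        else np.asarray(reference, dtype=float)
    )
    coords = ensemble.coords
    if fit:
        coords = _fit_frames(coords, ref, idx)
    sub = coords[:, idx, :]
    target = sub.mean(axis=0) if reference_mode == "mean" else ref[idx]
    vals = np.sqrt(np.mean(np.sum((sub - target) ** 2, axis=2), axis=0))
    return RmsfProfile(
        values=vals, atom_ids=idx, reference_mode=reference_mode, selection=str(selection)
    )


def rmsf_by_residue(ensemble: Ensemble, profile: RmsfProfile):
    """Aggregate a per-atom RMSF profile to residue level (mean over atoms).

    Returns (residue indices, per-residue RMSF) in first-appearance order,
    mirroring the residue-level fluctuation profiles commonly plotted.
    """
    res = ensemble.topology.resindices[profile.atom_ids]
    order: dict[int, list] = {}
    for r, v in zip(res, profile.values):
        order.setdefault(int(r), []).append(v)
    keys = np.array(list(order), dtype=int)
    vals = np.array([np.mean(order[k]) for k in keys])
    return keys, vals
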