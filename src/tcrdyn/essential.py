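"""Essential dynamics: positional covariance, eigen-decomposition,
low-dimensional projections and common subspaces across systems.

The covariance matrix of selected atomic positions (usually the alpha
carbons) is built after superposing every frame onto the ensemble mean
(two fitting passes: fit to the first frame, recompute the mean, fit to
that mean). Diagonalising it yields eigenvectors — the collective motion
modes — and eigenvalues (nm^2) sorted descending. Concatenating the
trajectories of systems with equal selected-atom counts gives common
eigenvectors, so the conformations explored by different systems can be
compared in one 2D projection plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fluctuations import superpose
from .model import Ensemble, TrajectoryError, as_indices

__all__ = [
    "EssentialSubspace",
    "Projection2D",
    "covariance_matrix",
    "diagonalize",
    "essential_subspace",
    "variance_fraction",
    "project",
    "combined_subspace",
    "subspace_overlap",
]


@dataclass
class EssentialSubspace:
    """Eigenvectors/eigenvalues of a positional covariance matrix.

    ``eigenvectors`` has shape (3N, 3N) with orthonormal columns;
    ``eigenvalues`` (nm^2) are sorted descending. ``mean`` is the mean
    structure of the fitted ensemble and ``fit_reference`` the structure
    frames were last superposed onto (None when no fitting was done);
    both are needed to reproduce the projection convention exactly.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    mean: np.ndarray
    fit_reference: np.ndarray | None
    selection: str = ""
    systems: list = field(default_factory=list)
    trace: float = 0.0

    def __post_init__(self) -> None:
        lam = self.eigenvalues
        if np.any(np.diff(lam) > 1e-12):
            raise TrajectoryError("eigenvalues must be sorted descending")
        if lam.size and lam[-1] < -1e-8 * max(1.0, abs(lam[0])):
            raise TrajectoryError("covariance eigenvalues significantly negative")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise TrajectoryError("eigenvectors are not orthonormal")

    @property
    def label(self) -> str:
        return f"{self.selection}|{'+'.join(map(str, self.systems))}|{len(self.eigenvalues)}"


@dataclass
class Projection2D:
    """Per-frame coordinates (nm) along the leading eigenvectors."""

    coords: np.ndarray  # (T, k)
    system: str
    subspace_label: str


def _fitted_coords(coords: np.ndarray, fit: bool, n_passes: int = 2):
    """Superpose frames onto the iteratively refined mean.

    Returns (fitted coords, fit target used in the last pass or None).
    """
    if not fit:
        return coords, None
    target = coords[0]
    for _ in range(n_passes):
        fitted = np.stack([superpose(f, target)[1] for f in coords])
        target = fitted.mean(axis=0)
    # final fit onto the converged mean, so the stored fit reference
    # reproduces these coordinates exactly when projecting later
    fitted = np.stack([superpose(f, target)[1] for f in coords])
    return fitted, target


def covariance_matrix(ensemble: Ensemble, selection=None, fit: bool = True) -> np.ndarray:
    """3N x 3N positional covariance ⟨Δr Δrᵀ⟩ about the ensemble mean."""
    cov, _, _ = _covariance(ensemble, selection, fit)
    return cov


def _covariance(ensemble: Ensemble, selection, fit: bool):
    if ensemble.n_frames < 2:
        raise TrajectoryError("covariance needs at least 2 frames")
    idx = as_indices(ensemble.topology, selection)
    if len(idx) == 0:
        raise TrajectoryError("empty selection")
    sub = ensemble.coords[:, idx, :]
    fitted, fit_ref = _fitted_coords(sub, fit)
    flat = fitted.reshape(len(fitted), -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / len(flat)
    cov = 0.5 * (cov + cov.T)
    return cov, mean.reshape(-1, 3), fit_ref


def diagonalize(
    covariance: np.ndarray,
    mean: np.ndarray | None = None,
    fit_reference: np.ndarray | None = None,
    selection: str = "",
    systems=(),
) -> EssentialSubspace:
    """Eigen-decompose a symmetric covariance matrix into an EssentialSubspace."""
    covariance = np.asarray(covariance, dtype=float)
    if covariance.ndim != 2 or covariance.shape[0] != covariance.shape[1]:
        raise TrajectoryError("covariance must be square")
    if not np.allclose(covariance, covariance.T, atol=1e-10):
        raise TrajectoryError("covariance must be symmetric")
    lam, vec = np.linalg.eigh(covariance)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    n_atoms = covariance.shape[0] // 3
    if mean is None:
        mean = np.zeros((n_atoms, 3))
    return EssentialSubspace(
        eigenvectors=vec,
        eigenvalues=lam,
        mean=np.asarray(mean, dtype=float),
        fit_reference=fit_reference,
        selection=selection,
        systems=list(systems),
        trace=float(np.trace(covariance)),
    )


def essential_subspace(
    ensemble: Ensemble, selection=None, fit: bool = True, system: str = "system"
) -> EssentialSubspace:
    """Covariance + diagonalization in one call, with projection provenance."""
    cov, mean, fit_ref = _covariance(ensemble, selection, fit)
    return diagonalize(
        cov, mean=mean, fit_reference=fit_ref, selection=str(selection), systems=[system]
    )


def variance_fraction(subspace: EssentialSubspace, k: int) -> float:
    """Fraction of total positional variance captured by the first k modes."""
    lam = subspace.eigenvalues
    if not 1 <= k <= lam.size:
        raise TrajectoryError(f"k must be in [1, {lam.size}]")
    total = float(np.sum(lam))
    if total <= 0:
        warnings.warn("zero total variance; variance fraction defined as 0", stacklevel=2)
        return 0.0
    return float(np.sum(lam[:k]) / total)


def project(
    ensemble: Ensemble,
    subspace: EssentialSubspace,
    selection=None,
    k: int = 2,
    system: str = "system",
) -> Projection2D:
    """Project frames onto the first k eigenvectors of a subspace.

    Each frame is first superposed onto the subspace's fit reference
    (when the subspace was built with fitting), then centred on the
    subspace mean.
    """
    idx = as_indices(ensemble.topology, selection)
    sub = ensemble.coords[:, idx, :]
    if sub.shape[1] != subspace.mean.shape[0]:
        raise TrajectoryError(
            f"selection has {sub.shape[1]} atoms; subspace expects {subspace.mean.shape[0]}"
        )
    if subspace.fit_reference is not None:
        sub = np.stack([superpose(f, subspace.fit_reference)[1] for f in sub])
    dev = sub.reshape(len(sub), -1) - subspace.mean.reshape(-1)
    proj = dev @ subspace.eigenvectors[:, :k]
    return Projection2D(coords=proj, system=system, subspace_label=subspace.label)


def combined_subspace(
    ensembles, selections=None, systems=None, fit: bool = True
):
    """Common essential subspace of several systems.

    Selected atom counts must agree across systems (atom correspondence is
    by selection order); the covariance is built on the concatenated,
    jointly superposed ensemble with equal per-frame weighting. Returns
    (EssentialSubspace, list of per-system Projection2D).
    """
    if systems is None:
        systems = [f"system{i}" for i in range(len(ensembles))]
    if selections is None:
        selections = [None] * len(ensembles)
    subs = []
    for ens, sel, name in zip(ensembles, selections, systems):
        idx = as_indices(ens.topology, sel)
        subs.append(ens.coords[:, idx, :])
    counts = {name: s.shape[1] for name, s in zip(systems, subs)}
    if len(set(counts.values())) != 1:
        raise TrajectoryError(f"selected atom counts differ across systems: {counts}")
    concat = np.concatenate(subs, axis=0)
    fitted, fit_ref = _fitted_coords(concat, fit)
    flat = fitted.reshape(len(fitted), -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    cov = dev.T @ dev / len(flat)
    cov = 0.5 * (cov + cov.T)
    space = diagonalize(
        cov,
        mean=mean.reshape(-1, 3),
        fit_reference=fit_ref,
        selection="combined",
        systems=list(systems),
    )
    projections = []
    start = 0
    for s, name in zip(subs, systems):
        frames = s
        if fit_ref is not None:
            frames = np.stack([superpose(f, fit_ref)[1] for f in frames])
        dv = frames.reshape(len(frames), -1) - mean
        projections.append(
            Projection2D(
                coords=dv @ space.eigenvectors[:, :2],
                system=name,
                subspace_label=space.label,
            )
        )
        start += len(s)
    return space, projections


def subspace_overlap(
    proj_a: Projection2D, proj_b: Projection2D, n_cells: int = 50
) -> float:
    """Scalar overlap of two 2D projection clouds in a common subspace.

    The joint bounding box is divided into ``n_cells`` x ``n_cells``
    cells; the score is the Jaccard overlap of the two occupied-cell sets
    (1 = identical support, 0 = disjoint clouds).
    """
    if proj_a.subspace_label != proj_b.subspace_label:
        raise TrajectoryError("projections live in different subspaces")
    pts = np.concatenate([proj_a.coords[:, :2], proj_b.coords[:, :2]], axis=0)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)

    def cells(p):
        ij = np.floor((p[:, :2] - lo) / span * n_cells).astype(int)
        ij = np.clip(ij, 0, n_cells - 1)
        return set(map(tuple, ij))

    ca, cb = cells(proj_a.coords), cells(proj_b.coords)
    union = ca | cb
    if not union:
        return 0.0
    return len(ca & cb) / len(union)
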