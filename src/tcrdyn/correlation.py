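"""Dynamic cross-correlation maps with threshold classification.

C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|^2><|Δr_j|^2>), displacements taken
about the ensemble mean after superposition (same convention as the
essential-dynamics covariance). A pair is classified *correlated* when
C_ij > 0.75 and *anticorrelated* when -1 <= C_ij <= -0.25; everything in
between is *neutral* (non-correlation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .essential import _fitted_coords
from .model import Ensemble, TrajectoryError, as_indices

__all__ = [
    "CorrelationMatrix",
    "CORRELATED_THRESHOLD",
    "ANTICORRELATED_BAND",
    "cross_correlation_matrix",
    "classify_correlations",
    "region_block_summary",
]

#: classification bands: strictly greater than 0.75 is correlated;
#: the closed interval [-1, -0.25] is anticorrelated.
CORRELATED_THRESHOLD = 0.75
ANTICORRELATED_BAND = (-1.0, -0.25)

LABEL_CORRELATED = "correlated"
LABEL_ANTICORRELATED = "anticorrelated"
LABEL_NEUTRAL = "neutral"


@dataclass
class CorrelationMatrix:
    values: np.ndarray  # (N, N) in [-1, 1]
    atom_ids: np.ndarray
    selection: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=1e-10):
            raise TrajectoryError("correlation matrix must be symmetric")
        if np.any(v > 1 + 1e-8) or np.any(v < -1 - 1e-8):
            raise TrajectoryError("correlation entries must lie in [-1, 1]")


def cross_correlation_matrix(
    ensemble: Ensemble, selection=None, fit: bool = True
) -> CorrelationMatrix:
    """Normalized displacement-vector correlation between all atom pairs.

    Atoms with zero positional variance (frozen pseudo-atoms in synthetic
    fixtures) get correlation 0 against everything, with a warning, rather
    than NaN.
    """
    if ensemble.n_frames < 2:
        raise TrajectoryError("correlation needs at least 2 frames")
    idx = as_indices(ensemble.topology, selection)
    if len(idx) == 0:
        raise TrajectoryError("empty selection")
    sub = ensemble.coords[:, idx, :]
    fitted, _ = _fitted_coords(sub, fit)
    dev = fitted - fitted.mean(axis=0)
    # inner products of displacement vectors, summed over time
    dots = np.einsum("tia,tja->ij", dev, dev) / len(dev)
    var = np.diag(dots).copy()
    frozen = var <= 0
    if frozen.any():
        warnings.warn(
            f"{int(frozen.sum())} atoms have zero variance; their correlations are set to 0",
            stacklevel=2,
        )
    denom = np.sqrt(np.outer(np.where(frozen, 1.0, var), np.where(frozen, 1.0, var)))
    corr = dots / denom
    corr[frozen, :] = 0.0
    corr[:, frozen] = 0.0
    np.fill_diagonal(corr, np.where(frozen, 0.0, 1.0))
    corr = np.clip(0.5 * (corr + corr.T), -1.0, 1.0)
    # restore exact unit diagonal for live atoms after clipping
    np.fill_diagonal(corr, np.where(frozen, 0.0, 1.0))
    return CorrelationMatrix(values=corr, atom_ids=idx, selection=str(selection))


def classify_correlations(matrix: CorrelationMatrix) -> np.ndarray:
    """Label every entry correlated / anticorrelated / neutral.

    Boundary handling is exact: 0.75 itself is neutral, -0.25 itself is
    anticorrelated.
    """
    v = matrix.values
    if np.any(np.abs(v) > 1 + 1e-8):
        raise TrajectoryError("matrix entries outside [-1, 1]")
    labels = np.full(v.shape, LABEL_NEUTRAL, dtype=object)
    labels[v > CORRELATED_THRESHOLD] = LABEL_CORRELATED
    lo, hi = ANTICORRELATED_BAND
    labels[(v >= lo) & (v <= hi)] = LABEL_ANTICORRELATED
    return labels


def region_block_summary(
    matrix: CorrelationMatrix, region_map: dict
) -> pd.DataFrame:
    """Block statistics of the correlation map over region pairs.

    ``region_map`` maps region name -> positions *within the matrix*
    (indices into its atom axis). Regions must be disjoint. Off-diagonal
    blocks are summarized by mean correlation and the fractions of
    correlated / anticorrelated entries.
    """
    seen: set = set()
    for name, pos in region_map.items():
        s = set(np.asarray(pos, int).tolist())
        if seen & s:
            raise TrajectoryError(f"region {name!r} overlaps another region")
        seen |= s
    labels = classify_correlations(matrix)
    rows = []
    names = list(region_map)
    for i, a in enumerate(names):
        for b in names[i:]:
            ia = np.asarray(region_map[a], int)
            ib = np.asarray(region_map[b], int)
            block = matrix.values[np.ix_(ia, ib)]
            lab = labels[np.ix_(ia, ib)]
            if a == b:
                mask = ~np.eye(len(ia), dtype=bool)
                block, lab = block[mask], lab[mask]
            rows.append(
                {
                    "region_a": a,
                    "region_b": b,
                    "mean_correlation": float(block.mean()) if block.size else np.nan,
                    "fraction_correlated": float(np.mean(lab == LABEL_CORRELATED))
                    if lab.size
                    else np.nan,
                    "fraction_anticorrelated": float(np.mean(lab == LABEL_ANTICORRELATED))
                    if lab.size
                    else np.nan,
                    "n_pairs": int(block.size),
                }
            )
    return pd.DataFrame(rows)
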