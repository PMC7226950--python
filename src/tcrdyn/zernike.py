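"""3D Zernike descriptors of molecular shape and electrostatics.

A selected region (e.g. the MHC binding groove) is voxelized as a
union-of-spheres solid (atom radius + probe) on a cubic grid scaled to
fit inside the unit ball; the electrostatic potential — externally
supplied, or a uniform-dielectric Coulomb fallback — is sampled on the
surface voxels and split into positive and negative channels. Each
scalar voxel field is expanded in the orthonormal 3D Zernike basis
Z_nlm(r, theta, phi) = R_nl(r) Y_lm(theta, phi); collapsing the moments
over m, F_nl = sqrt(sum_m |Omega_nlm|^2), gives rotation-invariant
descriptor vectors whose Euclidean distance quantifies shape or
electrostatic (dis)similarity between regions, frames or systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

from .model import TrajectoryError

__all__ = [
    "VoxelGrid",
    "MomentSet",
    "ZernikeDescriptor",
    "DEFAULT_RADII",
    "voxelize_shape",
    "voxelize_electrostatics",
    "surface_voxels",
    "coulomb_potential",
    "zernike_moments",
    "zernike_invariants",
    "descriptor_distance",
]

#: Element -> van der Waals radius (nm); pseudo-atoms default to carbon.
DEFAULT_RADII = {"H": 0.12, "C": 0.17, "N": 0.155, "O": 0.152, "S": 0.18, "P": 0.18}
DEFAULT_RADIUS = 0.17
DEFAULT_PROBE = 0.14  # nm, water-probe inflation of the union-of-spheres surface
FILL_FRACTION = 0.7  # region is scaled to radius 0.7 of the unit ball
COULOMB_PREFACTOR = 138.935  # kJ mol^-1 nm e^-2, matches the energies module


@dataclass
class VoxelGrid:
    """Cubic M^3 scalar grid living in the unit cube [-1, 1]^3.

    ``center_nm`` and ``scale`` (unit length per nm) map physical
    coordinates into grid space: u = (x - center) * scale. Content is
    guaranteed to fit inside the unit ball by construction.
    """

    values: np.ndarray
    channel: str
    center_nm: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or len(set(self.values.shape)) != 1:
            raise TrajectoryError("voxel grid must be cubic")
        if not np.all(np.isfinite(self.values)):
            raise TrajectoryError("voxel grid contains non-finite values")
        if np.any(self.values < 0):
            raise TrajectoryError("voxel values must be >= 0")

    @property
    def side(self) -> int:
        return self.values.shape[0]

    def voxel_centers_unit(self) -> np.ndarray:
        m = self.side
        axis = (np.arange(m) + 0.5) * 2.0 / m - 1.0
        gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)


@dataclass
class MomentSet:
    """Complex 3D Zernike moments Omega_nlm for n <= order.

    ``data`` maps (n, l) -> complex array over m = -l..l. Conjugation
    symmetry Omega_{n l -m} = (-1)^m conj(Omega_{n l m}) holds for any
    real-valued input field.
    """

    order: int
    channel: str
    data: dict = field(default_factory=dict)

    def get(self, n: int, l: int, m: int) -> complex:
        return self.data[(n, l)][m + l]


@dataclass
class ZernikeDescriptor:
    """Rotation-invariant norms F_nl = sqrt(sum_m |Omega_nlm|^2)."""

    order: int
    channel: str
    index: list  # list of (n, l)
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise TrajectoryError("invariants must be >= 0")


def _radii_for(elements, radii=None) -> np.ndarray:
    if radii is not None:
        return np.asarray(radii, dtype=float)
    return np.array([DEFAULT_RADII.get(str(e), DEFAULT_RADIUS) for e in elements])


def voxelize_shape(
    coords: np.ndarray,
    elements=None,
    radii=None,
    grid_side: int = 64,
    probe: float = DEFAULT_PROBE,
    fill: float = FILL_FRACTION,
    supersample: int = 2,
) -> VoxelGrid:
    """Union-of-spheres voxelization of a set of atoms.

    A point is inside the solid when it lies within any sphere of radius
    (atom radius + probe). Each voxel holds the fraction of its
    ``supersample``^3 subpoints that are inside (1 = fully interior,
    0 = outside); ``supersample=1`` gives a plain binary indicator.
    Sub-voxel averaging suppresses the grid-alignment aliasing that would
    otherwise dominate the rotational-invariance error of the
    descriptors. The cloud is centred on its centroid and scaled so that
    everything fits within radius ``fill`` of the unit ball, leaving a
    margin against boundary truncation.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) == 0:
        raise TrajectoryError("voxelize_shape needs a nonempty (N, 3) coordinate array")
    r = _radii_for(
        elements if elements is not None else ["C"] * len(coords), radii
    ) + probe
    center = coords.mean(axis=0)
    extent = float(np.max(np.linalg.norm(coords - center, axis=1) + r))
    scale = fill / extent
    u = (coords - center) * scale
    ur = r * scale

    m = grid_side * max(1, int(supersample))
    axis = (np.arange(m) + 0.5) * 2.0 / m - 1.0
    fine = np.zeros((m, m, m), dtype=bool)
    h = 2.0 / m
    for k in range(len(u)):
        lo = np.searchsorted(axis, u[k] - ur[k] - h)
        hi = np.searchsorted(axis, u[k] + ur[k] + h)
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        ax = [axis[s] - u[k][d] for d, s in enumerate(sl)]
        if any(len(a) == 0 for a in ax):
            continue
        d2 = (
            ax[0][:, None, None] ** 2
            + ax[1][None, :, None] ** 2
            + ax[2][None, None, :] ** 2
        )
        fine[sl] |= d2 <= ur[k] ** 2
    if not fine.any():
        raise TrajectoryError("voxelization produced an empty grid (region too small?)")
    s = max(1, int(supersample))
    if s > 1:
        values = (
            fine.reshape(grid_side, s, grid_side, s, grid_side, s)
            .mean(axis=(1, 3, 5))
        )
    else:
        values = fine.astype(float)
    return VoxelGrid(values=values, channel="shape", center_nm=center, scale=scale)


def surface_voxels(grid: VoxelGrid) -> np.ndarray:
    """Boolean mask of occupied voxels with at least one empty 6-neighbour."""
    occ = grid.values > 0
    interior = np.ones_like(occ)
    for ax in range(3):
        for shift in (1, -1):
            rolled = np.roll(occ, shift, axis=ax)
            # voxels at the array boundary face the outside
            sl = [slice(None)] * 3
            sl[ax] = 0 if shift == 1 else -1
            rolled[tuple(sl)] = False
            interior &= rolled
    return occ & ~interior


def coulomb_potential(
    points_nm: np.ndarray, charge_coords_nm: np.ndarray, charges: np.ndarray,
    dielectric: float = 1.0,
) -> np.ndarray:
    """Uniform-dielectric Coulomb potential (kJ/mol/e) at given points."""
    diff = points_nm[:, None, :] - charge_coords_nm[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=2))
    r = np.where(r < 1e-6, 1e-6, r)
    return COULOMB_PREFACTOR / dielectric * (1.0 / r) @ np.asarray(charges, dtype=float)


def voxelize_electrostatics(
    coords: np.ndarray,
    charges=None,
    elements=None,
    radii=None,
    grid_side: int = 64,
    probe: float = DEFAULT_PROBE,
    external_potential=None,
    dielectric: float = 1.0,
):
    """Positive and negative electrostatic channels on the surface voxels.

    The potential is sampled at the surface voxels of the shape grid:
    either from an externally computed point cloud ``external_potential =
    (points_nm (K,3), values (K,))`` — e.g. a Poisson-Boltzmann map —
    assigned by nearest neighbour, or from the internal Coulomb fallback
    using per-atom ``charges``. Returns (positive VoxelGrid, negative
    VoxelGrid): phi+ = max(phi, 0), phi- = max(-phi, 0).
    """
    if charges is None and external_potential is None:
        raise TrajectoryError(
            "no charge source: supply per-atom charges or an external potential map"
        )
    shape = voxelize_shape(coords, elements=elements, radii=radii, grid_side=grid_side, probe=probe)
    surf = surface_voxels(shape)
    centers_unit = shape.voxel_centers_unit()[surf]
    centers_nm = centers_unit / shape.scale + shape.center_nm
    if external_potential is not None:
        from scipy.spatial import cKDTree

        pts, vals = external_potential
        _, nearest = cKDTree(np.asarray(pts, dtype=float)).query(centers_nm)
        phi = np.asarray(vals, dtype=float)[nearest]
    else:
        phi = coulomb_potential(centers_nm, np.asarray(coords, float), charges, dielectric)
    pos = np.zeros_like(shape.values)
    neg = np.zeros_like(shape.values)
    pos[surf] = np.maximum(phi, 0.0)
    neg[surf] = np.maximum(-phi, 0.0)
    mk = lambda v, ch: VoxelGrid(values=v, channel=ch, center_nm=shape.center_nm, scale=shape.scale)
    return mk(pos, "electrostatics+"), mk(neg, "electrostatics-")


@lru_cache(maxsize=None)
def _radial_coefficients(n: int, l: int) -> tuple:
    """Coefficients q_v of R_nl(r) = sum_v q_v r^(2v + l) (orthonormal form)."""
    if (n - l) % 2 or l > n:
        raise TrajectoryError(f"invalid (n, l) = ({n}, {l})")
    k = (n - l) // 2
    pref = (-1) ** k / 4.0**k * math.sqrt((2 * l + 4 * k + 3) / 3.0) * math.comb(2 * k, k)
    out = []
    for v in range(k + 1):
        num = math.comb(k, v) * math.comb(2 * (k + l + v) + 1, 2 * k)
        den = math.comb(k + l + v, k)
        out.append(pref * (-1) ** v * num / den)
    return tuple(out)


def _radial_poly(n: int, l: int, r: np.ndarray) -> np.ndarray:
    q = _radial_coefficients(n, l)
    r2 = r * r
    acc = np.zeros_like(r)
    for v in range(len(q) - 1, -1, -1):
        acc = acc * r2 + q[v]
    return acc * r**l


def zernike_moments(grid: VoxelGrid, order: int = 20) -> MomentSet:
    """Project a voxel field onto the 3D Zernike basis up to ``order``.

    Omega_nlm = (3 / 4 pi) * sum_voxels f(x) conj(Z_nlm(x)) dV, summed
    over nonzero voxels (all of which must lie inside the unit ball —
    guaranteed for grids built by the voxelizers here).
    """
    occ = grid.values != 0
    centers = grid.voxel_centers_unit()[occ]
    f = grid.values[occ]
    r = np.linalg.norm(centers, axis=1)
    if np.any(r > 1.0):
        raise TrajectoryError("grid content extends outside the unit ball; renormalize")
    dv = (2.0 / grid.side) ** 3
    # spherical angles; guard the origin voxel
    rs = np.where(r < 1e-12, 1e-12, r)
    theta = np.arccos(np.clip(centers[:, 2] / rs, -1.0, 1.0))
    phi = np.arctan2(centers[:, 1], centers[:, 0])

    data: dict = {}
    pref = 3.0 / (4.0 * np.pi) * dv
    for l in range(order + 1):
        # W[m, v] = conj(Y_lm) * f at every occupied voxel, m = 0..l
        w = np.empty((l + 1, len(f)), dtype=complex)
        for m in range(l + 1):
            w[m] = np.conj(sph_harm_y(l, m, theta, phi)) * f
        for n in range(l, order + 1, 2):
            rad = _radial_poly(n, l, r)
            pos_m = pref * (w @ rad)
            full = np.empty(2 * l + 1, dtype=complex)
            full[l:] = pos_m
            for m in range(1, l + 1):
                full[l - m] = (-1) ** m * np.conj(pos_m[m])
            data[(n, l)] = full
    return MomentSet(order=order, channel=grid.channel, data=data)


def zernike_invariants(moments: MomentSet) -> ZernikeDescriptor:
    """Collapse moments over m into rotation-invariant norms F_nl."""
    index = sorted(moments.data)
    values = np.array([np.sqrt(np.sum(np.abs(moments.data[nl]) ** 2)) for nl in index])
    return ZernikeDescriptor(
        order=moments.order, channel=moments.channel, index=index, values=values
    )


def descriptor_distance(d1: ZernikeDescriptor, d2: ZernikeDescriptor) -> float:
    """Euclidean distance between two invariant vectors (same order, channel)."""
    if d1.order != d2.order or d1.channel != d2.channel:
        raise TrajectoryError("descriptors differ in order or channel; not comparable")
    return float(np.linalg.norm(d1.values - d2.values))
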