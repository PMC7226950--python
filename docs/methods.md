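# Methods

This note records the models implemented in `tcrdyn`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions that make results reproducible.

## Data model and units

All coordinates are held in nanometres (file readers convert from the
Angstrom of PDB); energies in kJ/mol, charges in elementary charges,
times in ns. Residue numbering follows the author numbering of the input
file (1-based, insertion codes retained); atom indices are internal and
0-based and never appear in reports. Region membership (groove, peptide
P1..Pn, Vα, Vβ, Cα, Cβ, leaflets ...) is declared in a YAML config as
chain + residue ranges rather than guessed, because the complexes under
study differ in sequence and chain layout. The MHC binding groove is by
convention residues 1–175 of the HLA α chain.

Trajectory formats (PDB, GRO, XTC, DCD, multi-model PDB) are read and
written through MDAnalysis. XTC/DCD do not always carry usable
timestamps; the frame-saving stride is therefore user-supplied metadata
(`dt_ns`), and an explicit stride always wins over file times. The
pipeline driver discards the equilibration head (`trim_ns`, typically
50 ns for membrane-embedded complexes) before any analysis; the
analysis operations themselves never trim.

## Superposition and fluctuations

RMSD and RMSF use the literal definitions (mean over atoms per frame,
mean over frames per atom, both against a reference structure). Frames
are first superposed by a proper-rotation Kabsch fit over the analysis
selection; the fit selection may differ from the measured selection.
RMSF defaults to the *initial-structure* reference (the definition as
stated), with the time-average reference available as `reference_mode=
"mean"`; the mean-reference value is never larger, and the gap measures
net drift. Per-residue profiles average the atoms of each residue.

## Essential dynamics

The positional covariance is built after superposing every frame onto
the iteratively refined ensemble mean: fit to the first frame, recompute
the mean, fit to that mean (two passes), then one final fit so the
stored fit target reproduces the fitted coordinates exactly. That last
detail makes the projection-variance identity exact: projecting the
generating ensemble onto eigenvector *k* returns sample variance λ_k to
machine precision, and Σλ = tr(C) always. The full 3N×3N matrix is
diagonalized directly (`eigh`); at desk scale (hundreds of atoms) no
iterative solver is needed.

Common subspaces concatenate the selected coordinates of several systems
(equal atom counts required; correspondence is by selection order, i.e.
region-relative index). Systems are weighted per frame, not per system —
the covariance of the concatenation — since no weighting convention is
canonical; with equal frame counts the two coincide. The overlap of two
projection clouds is the Jaccard overlap of occupied cells on a 50×50
grid spanning the joint bounding box: 1 for identical support, 0 for
disjoint clouds. It is a reproducible scalar for what is usually judged
by eye from scatter plots; it saturates for very dense clouds and
depends mildly on the grid resolution (exposed as a parameter).

## Cross-correlation maps

C_ij is the normalized scalar product of displacement vectors about the
mean, using the same superposition convention as essential dynamics so
the map and the covariance stay consistent. Classification bands are
applied literally: strictly greater than 0.75 is correlated; the closed
interval [−1, −0.25] anticorrelated; everything else neutral
(non-correlation). Atoms with exactly zero variance (legitimately
present in synthetic fixtures) get correlation 0 with a warning rather
than NaN, so downstream block statistics stay finite. Block summaries
report the mean correlation and the correlated/anticorrelated fractions
for every region pair; within-region blocks exclude the diagonal.

## Contact networks

Residues are nodes; an edge joins two residues when their Cα–Cα distance
is *strictly* below the cutoff (default 0.6 nm, i.e. 6 Å — the wording
"lower than" is implemented as `<`). Degree is the contact count.
Closeness uses the Wasserman–Faust component-size scaling,
((n_c−1)/(n−1))·(n_c−1)/Σd, because contact graphs at 6 Å can
disconnect and unscaled closeness would then jump between frames;
networkx's `wf_improved` closeness implements exactly this form and is
cross-checked against a BFS oracle in the tests. Distributions are
accumulated over ~100 frames, sampled evenly spaced by default
(deterministic) or uniformly at random with a seed.

## Hydrogen bonds

Detection criteria are geometric: donor–acceptor distance ≤ 0.35 nm
and, when explicit hydrogens exist, hydrogen–donor–acceptor angle ≤ 30°.
These are the conventional trajectory-analysis defaults; both are
config. Cα-only and heavy-atom systems use the distance criterion alone.
Occupancy is detected frames over analysed frames per (partner residue,
peptide position) pair; a presence matrix thresholds occupancy at a
configurable minimum (default 0.1). Anchor analysis flags peptide
positions whose groove contacts reach a minimum occupancy, reporting
N-terminal (P1–P2) and C-terminal (P(n−1)–Pn) anchors — the conserved
pockets that fix the ligand ends — and central (≈P4–P5) TCR contacts
separately.

## 3D Zernike descriptors

The region is voxelized as a union of spheres (van-der-Waals radius by
element plus a 0.14 nm probe) on a cubic grid, centred on the selection
centroid and scaled so everything fits within radius 0.7 of the unit
ball (margin against boundary truncation). Each voxel holds the fraction
of its 2×2×2 subpoints inside the solid; this anti-aliasing is what
keeps the rotational-invariance error of the final descriptors below 1%
at grid side 64 — plain binary voxels leave ~1% alignment noise. The
electrostatic channels sample the potential on the surface voxels
(occupied voxels with an empty 6-neighbour), either from an externally
computed potential map (nearest-neighbour assignment from a point cloud,
the intended route when a Poisson–Boltzmann solution exists) or from the
built-in uniform-dielectric Coulomb sum, and split it into max(φ,0) and
max(−φ,0).

Moments Ω_nlm = (3/4π)∫ f(x) Z̄_nlm(x) dV are computed as Riemann sums
over nonzero voxels with the orthonormal radial polynomials of the
standard 3D Zernike construction (coefficients from the closed-form
binomial expression, cached) and scipy's orthonormal spherical
harmonics; negative m follows from conjugation symmetry. Invariants are
F_nl = sqrt(Σ_m |Ω_nlm|²); descriptor distance is Euclidean, defined
only for equal order and channel. Defaults: grid side M = 64, order
N = 20 (121 invariants) — large enough that rotation error is dominated
by voxelization, small enough to stay sub-second per descriptor.
Exact spherical symmetry cannot survive a cubic grid, so a centred ball
yields l ≠ 0 invariants at the 10⁻³–10⁻⁴ relative level, not exactly
zero; tests assert < 1% of the leading invariant.

## Membrane

Leaflets are assigned by the sign of z relative to the mean headgroup z
(midplane); robust clustering is unnecessary for the planar bilayers in
scope and a one-sided distribution raises a degenerate-bilayer error.
Thickness follows the GridMAT nearest-neighbour convention: the lateral
plane (box dimensions when present, else the headgroup bounding box) is
divided into n_x × n_y cells (default 100×100) and each cell's value is
z(nearest upper headgroup) − z(nearest lower headgroup), nearest in the
lateral plane. No interpolation: every cell has a value as long as both
leaflets are nonempty; an optional lateral-distance threshold flags
cells with no nearby lipid instead of zero-filling. The half-trajectory
comparison reduces each frame to its grid mean and reports mean ± σ per
half and their difference (single-frame halves are flagged
low-confidence). Minimum inter-selection distances use the
minimum-image convention for orthorhombic boxes.

## Interaction energies

Region-pair nonbonded energies are descriptive statistics, not dynamics:
plain-cutoff Coulomb (f = 138.935 kJ mol⁻¹ nm e⁻², optional uniform
dielectric) plus Lennard-Jones with Lorentz–Berthelot combination, over
cross pairs within 1.2 nm (the production-run nonbonded cutoff). No
Ewald summation — a deliberate divergence from how the forces would be
computed in the simulation itself, appropriate because the quantity is a
between-region coupling profile, and no 1–4 exclusions, because the
compared regions are never covalently bonded. Pairs closer than 0.01 nm
warn (clash) but are still summed. Parameters come from a whitespace
table (resname, atom, q, σ, ε; `*` rows are atom-name fallbacks); a toy
set ships for pseudo-atom fixtures.

## Synthetic generators

All generators are pure functions of (spec, seed). They emulate exactly
the statistical features the analyses measure, and nothing else:

- **Toy complexes** are Cα-only (one bead per residue), with regions as
  spatially segregated random coils and the peptide an extended strand
  between groove and variable domains; default region sizes are a 175-
  residue groove and Ig-domain-sized TCR regions, with a 9-mer peptide.
- **Gaussian ensembles** have population covariance Σ = Σ_k a_k v_k v_kᵀ
  + εI with orthonormal planted modes — essential dynamics and
  cross-correlation are second-moment methods, so Gaussian fixtures
  exercise them completely. A variant plants pairwise region
  correlations via bivariate-normal rigid displacements.
- **Bilayers** are headgroup point sets on jittered lateral grids with
  prescribed separation, sinusoidal undulation (in-phase or antiphase),
  z-noise, and an optional per-frame separation drift.
- **H-bond trajectories** place each donor–acceptor pair at its own
  site, bound (0.29 nm) or unbound (0.60 nm) per frame by a Bernoulli
  draw at the planted occupancy.

What they do *not* emulate: anharmonicity, conformational transitions,
solvent, realistic lipid packing, sequence-dependent energetics. Passing
tests therefore demonstrate that the analysis machinery recovers known
second-moment structure, occupancies and geometry correctly — not that
any biological conclusion drawn from real trajectories is right.

## Problem sizes and determinism

The test suite runs the parameter-recovery checks at 60 atoms × 20,000
frames (essential dynamics, correlation), 1,000 frames (H-bond
occupancy), 2,500 lipids on a 100×100 grid (membrane), and M = 64,
N = 20 with 20 random rotations (Zernike) — sizes at which sampling
error sits comfortably inside the asserted tolerances while the whole
suite stays around a minute of compute. The end-to-end pipeline check
runs two 60-residue systems × 2,000 frames through every applicable
stage twice and compares outputs byte for byte; stage CSVs use a fixed
`%.10g` float format and sorted JSON keys so determinism is a property
of the code, not of dictionary ordering. All stochastic tests fix seeds;
hypothesis-based property tests run derandomized.

## Known limitations

- The equal-atom-count requirement for common subspaces is enforced, but
  the atom correspondence is positional within the selection; aligning
  structurally homologous residues across diverged sequences is the
  user's responsibility via the region config.
- Voxel-grid descriptors are compared only at equal order and channel;
  there is no cross-resolution normalization.
- Periodic-image handling assumes orthorhombic boxes.
- The Coulomb fallback for electrostatic channels is a uniform-dielectric
  point-charge sum; for publication-grade electrostatic similarity an
  external Poisson–Boltzmann potential map should be supplied.
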