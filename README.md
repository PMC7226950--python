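# tcrdyn

Post-simulation analysis of peptide–MHC–TCR (pMHC–TCR) molecular-dynamics
ensembles.

When a T-cell receptor engages a peptide-loaded MHC class I molecule, the
interesting biology lives in the *statistics* of the trajectory: which
regions fluctuate, which collective modes dominate, how the TCR variable
(Vα/Vβ) and constant (Cα/Cβ) domains couple to the MHC binding groove,
which peptide positions stay hydrogen-bonded to the groove pockets, how
similar the groove's shape and electrostatics remain across complexes, and
what the supporting membrane does. `tcrdyn` packages that entire
post-processing workflow as a tested, reusable Python library with a thin
CLI, exercised end-to-end on synthetic ensembles with known ground truth.

## What it computes

For an ensemble of frames $r_i(t)$, $i = 1..N$ atoms, $t = 1..T$:

- **Fluctuations** — $\mathrm{RMSD}(t) = \sqrt{\tfrac1N \sum_i |r_i(t) - r_i^0|^2}$
  against a reference frame, and per-atom/per-residue
  $\mathrm{RMSF}_i = \sqrt{\tfrac1T \sum_t |r_i(t) - r_i^0|^2}$, after
  least-squares (Kabsch) superposition.
- **Essential dynamics** — PCA of the positional covariance
  $C = \langle \Delta r\, \Delta r^\top \rangle$ of selected atoms
  (usually Cα): eigenvectors are collective motion modes, eigenvalues
  (nm²) their variances. Trajectories of systems with equal selected-atom
  counts can be concatenated into a *common* subspace, and each system's
  2D projection cloud compared by a grid-overlap score.
- **Cross-correlation maps** —
  $C_{ij} = \langle \Delta r_i \cdot \Delta r_j \rangle / \sqrt{\langle|\Delta r_i|^2\rangle \langle|\Delta r_j|^2\rangle}$,
  classified *correlated* ($C_{ij} > 0.75$), *anticorrelated*
  ($-1 \le C_{ij} \le -0.25$) or neutral, with region-block summaries.
- **Contact networks** — residues are nodes, edges join Cα pairs closer
  than 0.6 nm; degree and component-scaled closeness centrality are
  accumulated over ~100 sampled frames.
- **Hydrogen bonds** — donor–acceptor distance ≤ 0.35 nm (plus a 30°
  hydrogen–donor–acceptor angle when hydrogens exist), per-pair occupancy
  tables, and anchor analysis of the peptide termini (P1–P2, P8–P9) vs
  central TCR contacts (P4–P5).
- **3D Zernike descriptors** — the binding groove (or any region) is
  voxelized as a union-of-spheres solid scaled into the unit ball; the
  field is expanded in the orthonormal 3D Zernike basis
  $Z_{nlm} = R_{nl}(r) Y_{lm}(\theta,\phi)$ and collapsed into
  rotation-invariant norms $F_{nl} = \lVert \Omega_{nl}^m \rVert_m$ for
  three channels: shape, positive and negative surface electrostatics.
- **Membrane** — GridMAT-style bilayer thickness on a (default) 100×100
  lateral grid from nearest upper/lower leaflet headgroups, half-trajectory
  thickness comparison, and periodic-aware minimum inter-selection
  distances.
- **Interaction energies** — cutoff (1.2 nm) Coulomb + Lennard-Jones
  region-pair energies ($f = 138.935\ \mathrm{kJ\,mol^{-1}\,nm\,e^{-2}}$,
  Lorentz–Berthelot combination) and their distributions for
  peptide–groove, peptide–TCR and TCR–groove pairs.
- **Synthetic ground truth** — generators for Cα toy complexes, Gaussian
  ensembles with prescribed low-rank covariance and region correlations,
  undulating bilayers, and H-bond trajectories with planted occupancies,
  so every analysis has a fixture whose right answer is known exactly.

## Worked example

```python
import numpy as np
from tcrdyn import make_toy_complex
from tcrdyn.essential import essential_subspace, variance_fraction
from tcrdyn.synthetic import ModeSpec, sample_ensemble

top, ref = make_toy_complex(
    {"groove": 20, "Valpha": 8, "Vbeta": 8, "Calpha": 8, "Cbeta": 7},
    "SLLMWITQC", seed=1)
q, _ = np.linalg.qr(np.random.default_rng(4).normal(size=(3 * top.n_atoms, 3)))
ens = sample_ensemble(top, ref,
    ModeSpec(modes=list(zip(q.T, [1.0, 0.5, 0.1])), epsilon=1e-6),
    5000, seed=5)
space = essential_subspace(ens, fit=False)
print(np.round(space.eigenvalues[:4], 4))
print(round(variance_fraction(space, 2), 3))
```

prints

```
[1.0118 0.5055 0.1006 0.    ]
0.938
```

— the three planted mode amplitudes (1.0/0.5/0.1 nm²) reappear as the
leading covariance eigenvalues, and the first two modes carry
(1.0+0.5)/1.6 ≈ 94% of the total positional variance, exactly as
constructed. The `examples/` directory holds one short script per
capability (fluctuations, essential dynamics, correlation maps, networks,
H-bonds, Zernike descriptors, membrane, energies, full pipeline), each
printing the numbers it computes and what they mean.

## Command line

```bash
tcrdyn simulate --what complex --outdir sim        # synthetic fixtures
tcrdyn rmsd --topology sim/system.pdb --trajectory sim/trajectory.pdb \
       --dt-ns 0.1 --out rmsd.csv
tcrdyn run study.yaml --outdir out                 # the full workflow
```

`run` executes every configured stage for every system in a YAML study
config (topologies, trajectories, region definitions, per-stage
parameters, equilibration trim, combined-ED groups) and writes flat
CSV/JSON tables plus a run manifest; identical config + seed reproduces
the outputs byte for byte.

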