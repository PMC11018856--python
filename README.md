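# xtalmd

Analysis toolkit for molecular-dynamics ensembles of **protein crystals**.

Crystalline MD — simulating a supercell of symmetry-related protein chains
in their experimental lattice — is the natural bridge between simulation
and crystallography: the same observables (B-factors, ordered water sites,
lattice order) exist on both sides. `xtalmd` implements the analysis layer
for such simulations:

- **Lattice model** — unit-cell geometry, C121 (C2) symmetry operators,
  supercell construction, and *inverse crystallographic transforms* that
  map each chain's center of mass back into the asymmetric-unit frame. The
  mean magnitude of those mapped displacements is the lattice disorder
  amplitude; for isotropic per-axis vibrations of size σ it equals the
  3-D Maxwell mean 2√(2/π)·σ ≈ 1.596 σ.
- **Ensemble metrics** — Kabsch superposition, RMSD/MSD against the crystal
  structure, iterative mean structure, fraction of native contacts Q,
  and the B-factor decomposition
  B = (8π²/3)·RMSF², with B_lattice (fluctuations after one global
  superposition of the whole supercell, including rigid-body chain motion)
  versus B_chain (each chain superposed to its own mean); their difference
  isolates the rigid-body contribution 8π²·σ_rb². Scalar covariance
  C_ij = ⟨Δr_i·Δr_j⟩ versus interatomic distance is fitted with an
  exponential decay A·e^(−d/ℓ) to detect liquid-like lattice motion, and a
  two-condition equilibration check (per-replica plateau, replica
  agreement) formalizes convergence calls.
- **Water sites** — local-alignment tracking of crystallographic water
  sites: each ordered water is anchored to nearby protein heavy atoms,
  followed through the trajectory by superposing its anchors, and scored
  by the fraction of frames with a water oxygen within the occupancy
  radius.
- **Dihedral features** — φ/ψ (Ramachandran) and χ1/χ2 (Janin) dihedrals,
  sin/cos featurization ((93+60)×2×2 = 612 features for the reference
  system), pairwise-Cα distance features, PCA, pooled-variance-standardized
  LDA feature importance, and 3×3 χ1×χ2 rotamer tables over {g+, t, g−}
  compared by total-variation distance.
- **MSM kinetics** — mini-batch k-means microstates, sliding-window
  transition counts at a lag, maximum-likelihood transition matrices,
  implied timescales t_i = −τ/ln λ_i, crisp PCCA coarse-graining, and a
  cross-validated GMRQ-style score for model selection.
- **Loop thermodynamics** — inter-residue distance distributions (50 bins
  on [2, 18] Å by default, i.e. 0.32 Å bins) with whole-chain bootstrap
  errors, free-energy profiles G(x) = −ln p(x) (k_BT units), Shannon
  entropy S = −Σ p_i ln p_i, and closed/intermediate/open state
  populations.
- **Function comparison** — per-residue thermal-deviation profiles from
  sampled structure pairs, ligand-induced deviation profiles from apo/holo
  homolog pairs, and their Pearson correlation.
- **Synthetic data** — seeded generators of crystal-like trajectories with
  known ground truth (rigid-body and spatially correlated internal noise,
  two-state Markovian loop distances, tethered waters with prescribed
  occupancy), so every analysis has a recovery test without running MD.

## Worked example

```python
import numpy as np
import xtalmd as x
from xtalmd.synthetic import SyntheticSpec, synth_crystal_trajectory

spec = SyntheticSpec(n_cells=(3, 3, 3), n_frames=50, n_template_residues=10,
                     sigma_int=0.2, sigma_rb=0.5, corr_length=0.0, seed=0)
ens, truth, extras = synth_crystal_trajectory(spec)

disp = x.inverse_lattice_transform(ens, extras["template"], spec.cell)
amp = x.disorder_amplitude(disp)
print(f"lattice disorder amplitude: {amp['amplitude']:.3f} A")

b_lat = x.bfactors(ens, mode="lattice")
b_chn = x.bfactors(ens, mode="chain")
print(f"B_lattice - B_chain: {(b_lat.b - b_chn.b).mean():.2f} A^2")
```

prints

```
lattice disorder amplitude: 0.795 A
B_lattice - B_chain: 19.53 A^2
```

The C121 3×3×3 supercell holds 108 chains. The disorder amplitude matches
the Maxwell-mean prediction 1.596 × σ_rb = 0.798 Å for the injected 0.5 Å
per-axis rigid-body noise, and the B-factor difference matches the
rigid-body term 8π²σ_rb² = 19.74 Å² to within sampling error — the
decomposition cleanly separates lattice vibrations from internal motion.

A two-state Markovian loop distance (switch rates 0.02/0.08 per frame,
true stationary split 80/20) analysed with `state_populations` returns

```
loop-state populations: closed 79.7%, intermediate 0.0%, open 20.3%
```

A thin CLI covers the shell-level workflows:

```bash
xtal simulate --n-cells 1 1 1 --n-frames 20 --out run
xtal lattice --traj run.pdb --ref run.ref.pdb --supercell 1 1 1 --out disorder.tsv
xtal thermo --traj run.pdb --pair 10:16 --out thermo.tsv
```

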