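# Methods

This note documents the models, conventions and numerical choices behind
`xtalmd`, and what the synthetic-data tests do and do not demonstrate.

## Lattice model

**Cartesian frame.** Cell vectors follow the monoclinic standard: **a**
along x, **b** along y, **c** in the x–z plane. For a general triclinic
cell the standard PDB orthogonalization is used (identical to gemmi's),
which reduces to the monoclinic convention when α = γ = 90°. The default
cell is the C121 cell of the reference PDZ-domain crystal
(a = 65.30 Å, b = 39.45 Å, c = 39.01 Å, β = 117.54°).

**Symmetry.** C121 carries four positions per cell: (x,y,z), (−x,y,−z),
and both composed with the C-centering translation (½,½,0). The operator
registry is a plain dict (P1 is included for testing) and is extensible;
the operator set is cross-checked against gemmi in the test suite.

**Inverse transforms and disorder.** Chains are assigned to lattice sites
at construction time and never reassigned (at the amplitudes of interest,
chains do not diffuse between sites). Per frame, the chain's mass-weighted
heavy-atom center of mass is fractionalized with the per-frame cell matrix
(reference cell when no box is recorded), the inverse of the site's
operator and integer cell translation is applied, and the result is
re-orthogonalized with the **reference** cell matrix, so displacements are
always expressed in the reference frame even when an NPT box reshapes.
Averaging of |displacement| is Cartesian. For isotropic per-axis Gaussian
vibrations of size σ_rb the amplitude has the 3-D Maxwell mean
2√(2/π)·σ_rb ≈ 1.596 σ_rb, which is the identity the recovery tests use.

## Superposition metrics and B-factors

Kabsch superposition (SVD with reflection correction) underlies every
alignment-dependent metric; collinear or too-small selections are
rejected. The mean structure is computed by iterated align-and-average
until the mean moves < 1e-6 Å, with a 100-iteration guard.

`B_lattice` superposes each whole supercell frame once (fitting on all
Cα) and measures per-atom fluctuations about the time mean, so rigid-body
chain motion contributes. `B_chain` superposes each chain onto its own
mean first. Both report B = (8π²/3)·RMSF² per Cα, averaged over chains.
With independent rigid-body noise of per-axis size σ_rb the difference is
8π²σ_rb² up to two small biases: the global fit removes the mean of the
chain translations (a 1/n_chains effect) and per-chain alignment absorbs
part of the internal fluctuation (a ~6/(3·n_atoms) effect). At the sizes
used in the tests (108 chains, ≥ 100-atom chains) both are ≲ 1%.

**Native contacts.** Q uses heavy-atom pairs < 4.5 Å between residues
with |i−j| ≥ 4, preserved at ≤ 1.2× the reference distance. All three
parameters are exposed; they are conventional hard-cutoff choices, not
fitted quantities.

## Covariance decay

The scalar covariance C_ij = ⟨Δr_i·Δr_j⟩ is accumulated over chains and
frames after per-chain superposition, binned by the mean-structure pair
distance in 2 Å bins. Least-squares superposition removes, to first order
in the displacement amplitude, the projection of each frame's displacement
field onto the six rigid modes of the chain. For a spatially correlated
field this filtering is not a cosmetic correction: it subtracts a
long-wavelength component and makes the raw binned covariance decay much
faster than the underlying kernel (and go negative at mid-range). The
decay length is therefore obtained by **forward-modelling the filter**:
the candidate kernel A·e^(−d/ℓ) (per Cartesian axis) is projected onto the
complement of the rigid-mode basis, its scalar pair covariance is binned
exactly like the data, and (A, ℓ) minimize the squared residual against
the measured bin means (A is profiled out linearly; ℓ by bounded scalar
minimization). The plain exponential fit to the bin means is returned
alongside for reference; on synthetic fields with ℓ = 11 Å it is biased
low by roughly a factor of two, while the projection-aware fit recovers ℓ
within a few percent. The analysis is flagged degenerate when off-diagonal
bin means are below 10% of the mean diagonal (per-atom variance) level, as
for independent noise.

## Equilibration check

Two conditions, evaluated on the trailing window (default: the last half)
of each replica's observable series: (i) the least-squares slope of every
replica is within 2 SE of zero, and (ii) all pairwise differences of
window means are within 2× the pooled SE. Standard errors come from a
moving-block bootstrap (block length √n, 200 resamples, seeded), which
keeps the thresholds honest under autocorrelation. The two conditions are
standard convergence heuristics; the 2-SE thresholds are this package's
quantitative rendering of them.

## Water sites

Each reference water oxygen is anchored to the protein heavy atoms within
4.0 Å; sites with fewer than 3 anchors are flagged and excluded from
preservation statistics. Per frame, the anchors are superposed onto their
reference positions and the fitted transform carries the site into the
frame; the site is occupied if any water oxygen lies within 1.4 Å
(minimum-image when box vectors are given). A site is preserved when its
occupancy is ≥ 0.5. All four parameters are configuration-exposed
defaults of the local-alignment approach, not fitted values.

## Dihedral features and projections

Dihedrals use the IUPAC atom quadruples and right-handed sign convention,
range (−180°, 180°]; collinear quadruples yield NaN rather than silent
zeros. Features are [sin, cos] of each angle, residue-major, (φ, ψ) before
(χ1, χ2), sin before cos; the order is serialized with fitted projection
models so projections are bit-reproducible. PCA is the thin SVD
(scikit-learn, full solver); LDA standardizes each feature by the pooled
within-group variance first (zero-variance features fall back to the
global variance and are flagged), and importance is the absolute
discriminant coefficient. Rotamer states bin χ into g+ = [0°, 120°),
t = [120°, 180°] ∪ (−180°, −120°), g− = [−120°, 0°); backbone dependence
of rotamer preferences is deliberately ignored. Tables are compared by
total-variation distance, ½·Σ|p−q| ∈ [0, 1].

## Markov state models

Counting is sliding-window (maximal data use at long lags) and never
crosses trajectory boundaries; chains of a supercell are treated as
independent trajectories. The default estimator is the non-reversible
maximum likelihood (row-normalized counts); the reversible option
symmetrizes counts first. States without counts are trimmed; a count
graph splitting into more than one closed communicating set is an error
naming the components (a spectrum computed across disconnected sets would
be meaningless). Implied timescales are t_i = −τ/ln λ_i for real
eigenvalues in (0, 1). Coarse-graining is crisp PCCA: vertices of the
eigenvector simplex are located by Gram–Schmidt selection and states are
assigned by maximal membership; this reproduces metastable lumping
without the full PCCA+ membership optimization. The GMRQ-style score
clusters microstates on the training trajectories, assigns held-out
trajectories to those centers, and sums the top m transition-matrix
eigenvalue magnitudes estimated on the held-out data; folds are split by
trajectory and everything is seeded.

## Loop thermodynamics

The reaction coordinate is a single inter-residue distance (Cα by
default). Histograms use 50 uniform bins on [2, 18] Å (0.32 Å width);
out-of-range samples are counted and reported but excluded from the
masses. Bootstrap errors resample whole chains when chain structure is
present — frames within a chain are autocorrelated, so frame-level
resampling would understate errors. Free energy is G = −ln p in k_BT
units (optionally kcal/mol at T = 289 K), shifted so the minimum is zero;
empty bins are undefined (NaN), never zero; errors propagate as δG = δp/p.
Entropy is the plug-in estimator S = −Σ p_i ln p_i in nats; its absolute
value depends on the bin count (maximum ln 50 ≈ 3.91 for 50 bins), which
is why the bin count is always reported with it. Note that a 50-bin
probability-mass estimator cannot exceed ln 50, so entropy values larger
than that must come from a different estimator scale (e.g. a density
rather than mass convention); this package implements the mass convention
literally. Default state intervals are closed < 6.5 Å, intermediate
[6.5, 10) Å, open ≥ 10 Å — a transparent fallback; externally supplied
cluster labels are the faithful mode when an embedding-space clustering
defines the states.

## Deviation profiles

The ensemble profile samples unordered structure pairs uniformly with
replacement (self-pairs excluded; exact enumeration available), superposes
each pair on all shared Cα and averages per-residue deviations. The
ligand-induced profile superposes holo onto apo per homolog pair on the
mapped Cα and averages on reference numbering; residues missing from a
pair are averaged over covering pairs only, and uncovered residues are
reported with coverage 0 and NaN, never as zeros. Residue mappings are
explicit two-column tables rather than computed alignments, so mapping
errors are visible instead of silent. Correlation is Pearson over the
residue intersection.

## Synthetic data: what it does and does not show

The generators emulate the statistical structure the analyses assume: an
ideal supercell; independent per-chain rigid translations N(0, σ_rb²I);
internal displacements with covariance σ_int²·e^(−d/ℓ) between atoms
(Cholesky factorization of the kernel on the ≤ 500-atom template, one
independent draw per Cartesian axis); a hidden two-state Markov chain
emitting Gaussian distances; waters tethered to three-atom anchors,
present with probability q and enforced ≥ 4 Å site separation. Defaults
mirror the reference study's geometry (the C121 cell, 3×3×3 supercell,
~0.5 Å rigid-body vibrations, ℓ = 11 Å correlation, 10 ns frame spacing);
the template is a schematic 50-residue helix with side-chain stubs, not a
real protein. Everything is bit-reproducible from the spec and seed.

Passing recovery tests therefore shows that the estimators are unbiased
and correctly scaled on data satisfying their own assumptions — frames
are i.i.d. in time (no kinetics in the crystal generator), noise is
Gaussian, chains are truly independent, rigid-body motion is pure
translation. Real crystal trajectories violate all of these to some
degree (autocorrelated frames, anharmonic motions, inter-chain coupling,
rigid-body rotation and box reshaping), so quantitative agreement on
synthetic data bounds estimator error, not force-field or sampling error.

## Problem sizes and numerical choices

Recovery tests run at sizes where the target tolerances are comfortably
resolved: ~10⁴ chain-frames for the disorder amplitude (2%), 2000 frames
of a 50-residue chain for the covariance decay (10%), 108 chains × 80
frames for the B-factor decomposition (5%), 10⁶ frames for the two-state
implied timescale (5%), and 10³ frames for water occupancies (binomial
error). Tolerances in tests follow the analytic error budget (sampling
error plus the alignment-leakage terms above). Ties in k-means assignment
break toward the lowest center index; all stochastic steps take explicit
seeds.

## Known limitations

- Only C121 and P1 space groups are registered; no diffraction-side
  computations (structure factors, re-indexing) are attempted.
- B-factors are isotropic; no anisotropic tensors.
- Crisp PCCA can mis-assign states lying near simplex edges for weakly
  metastable systems; the full PCCA+ optimization is out of scope.
- The water-site tracker scores prescribed sites only; it does not detect
  new ordered-water positions.
- UMAP and other nonlinear embeddings are consumed as externally computed
  sample × 2 tables, never computed internally.
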