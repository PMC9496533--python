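# Methods

This note records the model choices, parameter conventions and numerical
decisions behind `hemepocket`, and what the synthetic benchmarks do and do
not establish.

## Normal-coordinate structural decomposition

A heme site is reduced to the 25-atom Fe–porphyrin skeleton (Fe, 4 pyrrole
N, 4 meso CH, 16 pyrrole C).  Distortion is defined as the least-squares
rigid-body-free displacement from a planar equilibrium geometry, expressed
in an orthonormal basis of 12 displacement modes named saddling, ruffling,
doming, waving(x), waving(y), propellering, breathing and five further
in-plane patterns.  The decomposition is:

1. Kabsch superposition of the observed skeleton onto the reference
   (proper rotation only; a mirror image is fitted with residual, never
   with an improper transform);
2. projection of the flattened displacement d = x_aligned − x_ref onto the
   modes.  For an orthonormal basis the least-squares amplitudes are the
   per-mode dot products; the out-of-basis residual norm is reported.

Assumptions and conventions:

- **No mass weighting.** Modes are orthonormal in plain Cartesian
  displacement space, so amplitudes are structural displacements in Å
  (the units in which pocket–distortion errors are reported).
- **Single pass.** One superposition followed by one projection; no
  iterative re-fitting.  Because every mode in the shipped basis is exactly
  orthogonal to the six rigid-body patterns, the Kabsch optimum coincides
  with the generating transform for in-basis deformations and recovery is
  exact to machine precision even at 1 Å amplitudes; the documented 0.02 Å
  test tolerance is a safety margin for bases that lack this property.
- **Sign conventions** for out-of-plane amplitudes are tied to the pocket
  frame's z-orientation rule (below); they are internally consistent but
  not asserted to match any published sign convention.
- The basis is consumed as data (JSON: names, 25×3 reference, 12×75 mode
  matrix; orthonormality validated to 1e-8 on load).  The packaged basis is
  symmetry-constructed (see "Synthetic data"); a quantum-chemically derived
  basis in the same schema is a drop-in replacement.

## Curation filters

- Heme groups are recognized by compound ID (HEM, HEA, HEB, HEC, HEO);
  heme type is assigned from the compound ID (HEM/HEB→b, HEC→c, HEA→a,
  HEO→o) with a completeness check against a small marker set of peripheral
  atoms — if markers are missing the type is "unknown".  Full substituent
  chemistry is deliberately not re-derived.
- Axial ligands: any non-heme heavy atom within **3.1 Å** of the iron,
  *closed* interval (a contact at exactly 3.1 Å counts; the boundary had to
  be fixed for reproducibility).  The amino-acid flag is by residue name
  (standard 20 + MSE).
- Filters (one reason logged per rejection, in priority order): incomplete
  skeleton → missing resolution record → resolution > 2.0 Å → any
  non-amino-acid axial ligand.  Entries without a resolution record are
  rejected because the resolution filter cannot be evaluated for them.
- Multi-model files: first model; alternate locations: first conformer.
- Sequence redundancy: greedy scan in input order dropping chains whose
  global pairwise identity (matches / alignment columns, via Biopython
  global alignment; a bounded edit-distance prescreen skips hopeless pairs)
  to a kept chain is ≥ 99.99 %.  Clustering at 90 % uses greedy incremental
  cluster founding by descending length — an in-house replacement for
  external clustering servers that is equivalent at these extreme
  thresholds and removes the service dependency.

## Pocket frame and voxelization

The frame is anchored on the four meso carbons: origin at their mean,
xy-plane = their least-squares plane, x = unit projection of CHC−CHA onto
the plane, z-sign fixed by z·[(CHB−CHA)×(CHC−CHA)] > 0, y = z×x.  Direction
conventions (x from CHC−CHA rather than the reverse, the triple-product
z-sign) are arbitrary but fixed, so frames are reproducible across
implementations and rigid motions of the complex.

Occupancy grids: cube of edge 17/20/24 Å, 1 Å cells with cell i spanning
[−L/2+i, −L/2+i+1); four binary channels (C, N, O, S).  A cell is occupied
when a sphere of *half* the van-der-Waals diameter (C 0.85, N 0.775,
O 0.76, S 0.90 Å) around any protein atom of that element intersects the
**closed** cell cube.  The sphere-intersects-cell predicate (rather than
center-in-sphere) was chosen because the half-radii are smaller than half
the cell diagonal, so corner-adjacent atoms would otherwise vanish from the
grid.  Hydrogens are ignored (no channel); heme and every other non-protein
molecule are removed before rasterization.  Grid side equals the edge in
cells (20 Å → 20³ input), which is the only convention consistent with the
network's feature-map trace below.

Ablation masks operate on the 24 Å grid (outer cube half-width 12 Å):
"outside" discarding zeroes cells whose centers fall outside the inner cube
of half-width 12−r; "inside" discarding zeroes centers inside the cube of
half-width r (0 ≤ r < 12).  Cell centers sit at half-integer coordinates,
so no center ever lies on an integer-r cube face; the inner cube is treated
as closed.  The retained volume is (24−2r)³ or 24³−(2r)³ respectively.

## The regressor

Fixed architecture (input side L ∈ {17, 20, 24}, 1 or 4 channels, output
1 or 12 amplitudes):

| stage | operation | L = 20 trace |
|---|---|---|
| 1 | conv 64, kernel 2, pad 1 | 21³ |
| 2 | conv 128, kernel 2, pad 1 | 22³ |
| 3 | batch-norm | 22³ |
| 4 | conv 128, kernel 2, no pad | 21³ |
| 5–6 | ReLU, batch-norm | 21³ |
| 7 | max-pool kernel 2 stride 2 | 10³ |
| 8 | flatten | 128 000 |
| 9–11 | linear 128, ReLU, dropout 0.4 | |
| 12–14 | linear 64, batch-norm, ReLU | |
| 15 | linear out | 1 (or 12) |

Stride 1 and one voxel of zero padding on each face of the two padded
convolutions is the only assignment that reproduces this trace with
kernel 2.  Kernel-2 convolutions are spatially asymmetric; the offset
(0,0,0) corner of the kernel is aligned with the output cell.  Flattened
width is 128·s³ with s = ⌊(L−1)/2⌋+1 (93 312 / 128 000 / 221 184 for
L = 17/20/24), asserted against a live forward pass.

Training: Adam, learning rate 0.01, batch 32, mean-square-error loss,
binary grids fed as-is (no input normalization).  Per-epoch reshuffling,
dropout masks and weight initialization (uniform ±1/√fan_in) all draw from
one seeded generator, so runs are bitwise reproducible on a machine.  The
parameters (including batch-norm running statistics) of the epoch with the
minimal validation loss are retained, earliest epoch on ties.  Divergence
(non-finite loss) aborts with a diagnostic rather than returning garbage.

Cross-validation: shuffle, split into k = 5 subsets; each subset is divided
0.2/0.8 into validation and test parts, the model trains on the other four
subsets, and the min-validation model is scored on the test part (R², RMSE,
and per-heme-type RMSE when type labels exist).  All index sets are kept on
the report for audit.  The ablation re-scores trained fold models on masked
copies of their test inputs; at r = 0 the mask is the identity and the row
reproduces the baseline exactly.

The engine behind this is a purpose-built numpy implementation: kernel-2
conv3d evaluated as eight shifted views gathered into an im2col matrix and
one BLAS GEMM (micro-batched to bound scratch memory), with analytic
gradients verified against finite differences and an independent
shift-enumeration oracle in the test suite.  Activations are float32,
channels-last.  Scratch buffers are pooled because allocation, not
arithmetic, otherwise dominates single-core runtime.

## Cavity analysis

Complexes are superposed on five heme core atoms (FE, NA–ND) onto the
reference porphyrin.  The cavity vector enumerates the integer lattice
points (1 Å spacing) with |p| ≤ 8.5 Å of the iron — 2 553 points, fixed
lexicographic order — and sets a bit where the point is farther than the
*full* van-der-Waals radius (C 1.70, N 1.55, O 1.52, S 1.80 Å; 1.80 Å for
other heavy elements) from every protein heavy atom.  Full radii are used
here, unlike the voxelizer's half-radii, because cavity detection needs
physical exclusion volumes; no probe radius or contiguity flood-fill is
applied.  The 8.5 Å radius matches the heme's own extent (Fe to propionate
oxygens).

Similarity is the Tanimoto score |v∧w|/|v∨w| (two empty vectors count as
identical).  Clustering: agglomerative, average linkage on 1 − Tanimoto,
cut at a fixed cluster count (35 for corpus-scale runs).  Within-cluster
PCA is plain mean-centered SVD of the bit vectors; component signs are
fixed (largest-magnitude loading positive) so results are independent of
member order, and loadings are exportable per lattice point.  Correlation
of PC scores with NSD amplitudes uses Pearson r with the regression line.
Cluster dispersion is d̄_I = (1/N_I)Σ‖vᵢ − μ_I‖ with the Euclidean norm.

"Heme coverage" — used to exclude pockets split across asymmetric units —
is operationalized as the fraction of the 25 skeleton atoms with at least
one protein heavy atom within 5.0 Å, filtered at 0.6.  Missing protein
atoms are *not* rebuilt (no structure-completion step); incomplete chains
are used as-is.

## Synthetic data

The generator emulates the curated corpus in the features the pipeline
consumes, and nothing else:

- **Reference porphyrin**: idealized planar fourfold-symmetric skeleton
  (Fe–N 2.01 Å, meso radius 3.42 Å, β-carbon radius 4.30 Å).
- **Mode basis**: symmetry-adapted displacement patterns (whole-pyrrole
  alternation for saddling, meso alternation for ruffling, ring-vs-Fe for
  doming, cubic-radial waves for waving — a pure linear tilt would be a
  rigid rotation — within-pyrrole twist for propellering, radial/tangential
  patterns including uniform-radial breathing), projected off the exact
  rigid-body subspace and Gram-Schmidt orthonormalized.  Orthonormal to
  1e-10 by construction; the low modes are purely out-of-plane, breathing
  purely in-plane.
- **Pockets**: two pseudo-protein sheets at z = ±3.5 Å whose local height
  follows gain × (out-of-plane displacement of the nearest skeleton atom),
  clamped to keep ≥ 2.8 Å clearance from the local heme surface (the
  clamped branch still tracks the displacement monotonically, with slope 1
  instead of gain); a 3-ring peripheral wall at radius 9.2 Å enclosing the
  macrocycle; one histidine-like NE2 coordinating the iron at 2.05 Å from
  below.  Elements are drawn C/N/O/S ≈ 0.62/0.15/0.18/0.05; every pocket
  atom gets isotropic Gaussian jitter σ.
- **Study conditions**: σ = 0.1 Å; amplitudes uniform on [−1, 1] Å for
  saddling, ruffling, doming and waving(y), zero elsewhere; coupling gain
  6.0, chosen once so a full-range amplitude moves walls by ≈ ±1.8 Å,
  i.e. about two voxel cells — resolvable but not trivial at the 1 Å grid
  pitch.  Heme compound IDs are drawn HEM/HEC ≈ 0.7/0.3 so per-type metrics
  are exercised.
- **Defects** for filter testing (all off by default): water axial ligand
  at 2.5 Å, deleted FE record, a 2.5 Å resolution tag (resolution is
  metadata only; no diffraction is simulated), duplicated chain sequences.
  Synthetic FASTA sequences are random 120-mers.
- Whole complexes are emitted under random rigid motions as standard PDB
  files (bit-identical for identical config and seed), with a manifest of
  true amplitudes.  An end-to-end audit in the tests confirms NSD on the
  emitted files reproduces the manifest amplitudes to < 0.02 Å.

What the synthetic benchmarks show: that every stage of the implementation
is faithful (parsers, filters, NSD, frames, grids, training, masking,
cavity statistics) and that the pipeline detects a geometric
pocket–distortion coupling when one exists and reports none when it does
not (gain-0 control).  What they do not show: anything about real proteins
— the generator has no folds, no side-chain chemistry, no crystallographic
noise model, and its pocket–distortion coupling is injected by
construction, not discovered.

## Reproduction study sizes

The bundled studies (`hemepocket.studies`, exercised by the acceptance
script and suite) run at sizes chosen for single-CPU wall-clock budgets:
parameter recovery with n = 240 samples, 17 Å grids, 12 epochs (validation
R² plateaus well before that; held-out R² ≈ 0.9 against an acceptance bar
of 0.5); the gain-0 control at the same n with 6 epochs; the mask-identity
check with n = 60 at 24 Å and 2 epochs (the r = 0 identity is exact for any
parameters); PC1–distortion correlation on a 40-sample saddling-only
cluster.  Larger corpora and epoch counts scale linearly in time and were
not needed for any conclusion the package draws.

## Known limitations

- The curation layer trusts deposited compound IDs and atom names; no
  chemical perception is attempted.
- NSD uses 12 modes only; genuinely out-of-basis deformation appears in
  the residual, not the amplitudes.
- Even-kernel convolutions make the network's receptive field spatially
  asymmetric by half a voxel; this is inherent to the architecture.
- Average linkage and the 35-cluster cut are conventions; cavity
  clusterings at other settings will differ.
- The synthetic sequence model is random strings; redundancy reduction is
  exercised structurally (exact duplicates, near-identity arithmetic), not
  phylogenetically.
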