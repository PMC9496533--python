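# hemepocket

Tools for studying how the tertiary structure of a heme-binding pocket
shapes the out-of-plane distortion of the bound heme porphyrin.

Heme proteins tune the chemistry of their cofactor partly by deforming the
Fe–porphyrin macrocycle: saddling and ruffling shift redox potentials,
doming accompanies oxygen binding.  `hemepocket` implements the full
analysis chain for asking whether the *shape* of the protein environment
around a heme predicts that deformation:

1. **Curation** — read mmCIF/PDB files, pull out heme groups (compound IDs
   HEM/HEA/HEB/HEC/HEO), validate the 25-atom Fe–porphyrin skeleton, detect
   axial ligands of the iron (contacts within 3.1 Å), and filter: resolution
   ≤ 2.0 Å, no non-amino-acid axial ligand, complete skeleton; sequence
   redundancy is removed by greedy global-identity screening (99.99 %) and
   chains can be clustered at 90 % identity.
2. **NSD** — normal-coordinate structural decomposition: after rigid
   (Kabsch) superposition onto a planar reference porphyrin, the
   75-dimensional displacement is projected onto 12 orthonormal displacement
   modes (saddling, ruffling, doming, waving(x/y), propellering, breathing,
   …), giving amplitudes in Å.
3. **Voxelization** — a heme-anchored frame is built from the four meso
   carbons; the protein environment (heme and all other molecules removed)
   is rasterized into a binary occupancy cube (edge 17/20/24 Å, 1 Å cells,
   one channel each for C/N/O/S with half-van-der-Waals radii).
4. **Regression** — a 3-D convolutional network
   (conv64 → conv128 → BN → conv128 → ReLU → BN → maxpool → FC128 → dropout
   0.4 → FC64 → BN → FC out) maps the voxel cube to the distortion amplitude
   p̂; trained with Adam (lr 0.01, batch 32, MSE), model selection by
   minimum validation loss, evaluated by R² = 1 − Σ(pᵒᵇˢ−p̂)²/Σ(pᵒᵇˢ−p̄)²
   and RMSE (Å) under five-fold cross-validation.  An ablation masks cubic
   regions of the input ("outside"/"inside" discarding) to localize where
   the predictive signal lives.
5. **Cavity analysis** — pocket shapes as bit vectors over the integer
   lattice inside an 8.5 Å sphere on the iron, compared by Tanimoto score,
   clustered (average linkage on 1 − Tanimoto), examined by per-cluster PCA
   against distortion, and summarized by the barycenter dispersion
   d̄_I = (1/N_I) Σᵢ ‖vᵢ − μ_I‖.
6. **Synthetic data** — a generator that emits standard PDB files of planar
   porphyrins deformed along known mode amplitudes inside procedurally
   built pockets whose wall relief deterministically encodes those
   amplitudes, so every stage above is testable without any downloads.

The convolutional engine itself (kernel-2 conv3d as im2col GEMMs,
batch-norm, max-pool, dropout, Adam) is implemented in numpy inside the
package; training runs are exactly reproducible for a fixed seed.

## Worked example

```python
import numpy as np
from hemepocket import (GeneratorConfig, generate_dataset, curate_corpus,
                        DistortionCNN, TrainConfig)

# 240 synthetic heme proteins; wall geometry encodes the true amplitudes
cfg = GeneratorConfig(n=240, seed=11)
samples, manifest = generate_dataset(cfg, None)

# curate -> NSD labels -> 17 A voxel grids
ds = curate_corpus(samples, edge=17)

model = DistortionCNN(ds.grids, ds.amplitude("saddling"),
                      cfg=TrainConfig(epochs=12, seed=8))
res = model.fit(val_fraction=0.1, test_fraction=0.2, seed=7)
print(res.summary())
print(res.test_score())
```

which prints:

```
Pocket-voxel distortion regression (3-D CNN)
==============================================
input                4 x 17^3 voxels (1 A cells)
output dim           1
flat features        93312
optimizer            Adam, lr 0.01, batch 32
epochs               12 (best: 11)
best val MSE         0.01094 A^2
n train/val/test     168/24/48
{'r2': 0.9679006118316772, 'rmse': 0.1027778842380528}
```

i.e. on 48 held-out synthetic pockets the network recovers the saddling
amplitude with R² ≈ 0.97 and an error of ≈ 0.10 Å — distortion is readable
from pocket shape whenever the generator couples the two (setting the
coupling gain to 0 collapses held-out R² to ≤ 0).

A thin CLI mirrors the library: `hemepocket synth | curate | nsd |
voxelize | crossval | cavity` (see `hemepocket --help`).

## Layout

- `src/hemepocket/curation.py` — structure reading, heme extraction, filters,
  sequence redundancy
- `src/hemepocket/nsd.py` — mode basis, Kabsch superposition, decomposition
- `src/hemepocket/voxel.py` — pocket frame, occupancy grids, ablation masks
- `src/hemepocket/nnet.py` — the numpy conv-net engine
- `src/hemepocket/regress.py` — architecture, training, CV, ablation,
  `DistortionCNN`/`DistortionCNNResults`
- `src/hemepocket/cavity.py` — cavity vectors, Tanimoto, clustering, PCA,
  dispersion
- `src/hemepocket/synthetic.py` — reference porphyrin, synthetic mode basis,
  pocket generator
- `src/hemepocket/workflow.py`, `studies.py`, `cli.py` — pipeline glue,
  reproduction studies, command line
- `docs/methods.md` — model assumptions, parameter choices, limitations
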