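# ihcmap

Semi-quantitative myelin-, microglia- and cell-density mapping from tiled
brightfield immunohistochemistry (IHC) whole-slide images, and co-registration
of the resulting maps (plus annotation masks) to high-resolution *ex vivo* MRI
volumes.

The package is written for post-mortem neuropathology studies — multiple
sclerosis brain blocks in particular — where a slide stained with hematoxylin
(nuclei), DAB (MHC-II microglia/macrophages) and fast blue (myelin) must be
turned into per-region counts that can be compared voxel-by-voxel with MRI
contrasts of the same tissue block. Every stage is scriptable and tested
against synthetic phantoms with full ground truth, so no slide scanner, OMERO
server or GUI is needed to run or validate the pipeline.

## The model

Brightfield color formation follows the monochromatic Beer–Lambert law. A
pixel with background intensity `I0_c` in channel `c` and stain concentrations
`C` is observed at

```
I_c = I0_c · 10^(−(C·M)_c)
```

where `M` is the 3×3 optical-density stain matrix whose rows are the unit-norm
OD color vectors of the three chromogens. Writing the per-pixel OD as
`Y = C·M`, the deconvolution matrix `D = M⁻¹` recovers the per-stain
concentrations, `C = Y·D`. `M` is estimated blindly from the slide itself by a
Bayesian K-SVD scheme (sparse coding of pixel OD vectors against a 3-atom
dictionary, alternated with rank-1 dictionary updates, plus an empirical
refinement pass), initialized from reference stain vectors.

Around that core the pipeline provides:

* **Preprocessing** — global CIELAB L-channel normalization; background
  removal at the largest frequency drop of the global OD histogram (46 bins,
  10 % pixel sampling); flat-field correction of the radial vignette /
  mosaicking artifact from a polynomial gain surface over intra-tile position.
* **Detection** — multi-pass connected-component rules for nuclei and
  microglia (MAD threshold, size/intensity filters, intensity-weighted
  centroid trimming, distance-transform watershed) and Wolf adaptive
  thresholding (`T = m − k·(1 − α·s/R)·(m − min)`) for myelin-positive pixels.
* **Density maps** — per-small-tile counts (360×360 px ≈ 100×100 µm tiles)
  rendered as 36×36 px blocks, matching the MRI voxel scale.
* **Registration** — best-slice matching by NMI/NCC/SSIM/ORB-feature scores,
  orientation ranking over the 8 dihedral operations by HOG similarity, 6-dof
  affine coarse alignment, landmark thin-plate-spline refinement
  (`U(r) = r² log r`), transform propagation to derived maps and masks, and
  splitting of annotation masks into ~500-voxel connected subregions for
  patch-wise analysis.
* **Phantoms** — seeded generators of IHC tile grids, detection tiles and
  MRI-like volumes with exact ground truth (stain matrix, concentration maps,
  object counts, vignette gain, deformation fields).

## Worked example

```python
import numpy as np
from ihcmap import phantoms, preprocess, stains, detect, density

# synthesize a small stained slide with known ground truth
phantom = phantoms.gen_ihc_phantom(seed=42, grid=(3, 3), tile_px=256, od_noise_sigma=0.02)

# background separation on the optical-density histogram
bg = preprocess.estimate_background(phantom.tiles, seed=0)
tiles = preprocess.remove_background(phantom.tiles, bg)
print(f"I0 = {tuple(round(v, 1) for v in bg.I0)}, OD threshold = {bg.od_threshold:.4f}")

# blind stain separation, initialized from the built-in reference vectors
model, report = stains.estimate_stain_vectors(
    tiles, init=stains.StainModel(stains.DEFAULT_STAIN_MATRIX),
    od_threshold=bg.od_threshold, i0=bg.I0, seed=0,
)
print(f"converged = {report.converged} after {report.n_iterations} iterations")
for label, row in zip(model.labels, model.M):
    print(f"  {label:12s} OD vector = {np.round(row, 3)}")

# count nuclei on a detection tile and render a density map
conc, truth = phantoms.gen_detection_tile(seed=7, n_nuclei=15, tile_px=360)
cells = detect.detect_cells(conc, detect.CellParams())
print(f"nuclei: detected {cells.count}, ground truth {truth['counts']['nuclei']}")
maps = density.build_density_map(np.array([[cells.count]]), kind="cell")
print(f"density map block: {maps['raw'].image.shape}, total count {maps['raw'].values.sum()}")
```

Output:

```
I0 = (246.3, 246.3, 244.8), OD threshold = 0.0071
converged = True after 2 iterations
  hematoxylin  OD vector = [0.65  0.706 0.283]
  dab          OD vector = [0.268 0.563 0.782]
  fastblue     OD vector = [0.925 0.342 0.163]
nuclei: detected 15, ground truth 15
density map block: (36, 36), total count 15
```

The recovered OD vectors match the phantom's generating stain matrix to a
fraction of a degree; the detector recovers the exact nucleus count; the
density map renders one uniform 36×36 block per analysis tile.

The same pipeline is available from the shell via the `ihcmap` command
(`ihcmap phantom ihc`, `ihcmap preprocess background`, `ihcmap stains
estimate`, `ihcmap detect cells`, `ihcmap register slice`, …); run
`ihcmap --help` for the full tree.

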