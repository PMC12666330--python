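# Methods

This note documents the models, parameters, numerical choices and known
limitations of `ihcmap`. It is the companion to the API docstrings: the
docstrings say *what* each function computes, this note says *why* it is
computed that way and what the phantom-based validation shows.

## Color model and stain separation

Brightfield IHC is modelled by the monochromatic Beer–Lambert law: per pixel
and RGB channel `c`, the transmitted intensity is
`I_c = I0_c · 10^(−Y_c)` with OD `Y = C·M`, where the rows of the 3×3 stain
matrix `M` are unit-l2 OD color vectors of the chromogens and `C` holds the
per-stain concentrations. Deconvolution is `C = Y·M⁻¹`. Intensities below 1
are clamped before the log so saturated pixels stay finite; sentinel
background pixels (exactly RGB 255,255,255 after background removal) are
excluded from every statistic downstream.

Chromogen separation is limited to three stains by the dimensionality of RGB;
the default vectors are the standard hematoxylin and DAB directions plus a
red-absorbing fast-blue direction well separated from both (pairwise angles
27–55°).

**Blind estimation (`stains.estimate_stain_vectors`).** Pixel OD vectors
above the background threshold are sparse-coded against the 3-atom dictionary
with at most two active stains per pixel; atoms are refreshed by rank-1 SVD
(K-SVD) updates and re-normalized each iteration. Three details matter in
practice:

* *Sparsity pruning.* A second atom is accepted for a pixel only when it cuts
  the residual below half of the single-atom residual **and** that residual
  exceeds a noise floor tracking the running median residual (the pruning
  role the sparsity prior plays in the variational formulation). Without it,
  nearly every pixel picks up a spurious second atom that merely fits
  quantization noise and drags the dictionary update.
* *Monotone error guard.* A dictionary update that increases the coding error
  is reverted and the iteration stops, so the reported per-iteration error
  sequence is non-increasing by construction.
* *Refinement.* After convergence, each atom is optionally re-anchored on the
  pixels its stain explains essentially alone ("pure-pixel snap", accepted
  only when the hard coding error decreases), and ambiguous pixels (two
  leading loadings within a 0.8 ratio) are re-coded with a hard single-atom
  assignment followed by one more dictionary update.

Defaults: `max_iter 50`, relative-change tolerance `1e-5`, ambiguity ratio
`0.8`, 30 000 sampled pixels. Initialization is from reference stain vectors
(the recommended workflow), from the OD cloud's clustered extreme directions
(`"data"`), or from NMF (`"nmf"`).

**Accuracy.** On slide phantoms with OD noise σ=0.02 and a reference
initialization ~8° off the generating vectors, recovery is typically 0.5–5°
per stain. Roughly a third of random condition draws stall at 5–9° on one
stain: when an atom's initialization error is expressible as a *positive*
combination of co-occurring atoms, the ≤2-atom non-negative coding objective
is flat (or even slightly favorable) along that direction, so no descent
method can remove it. This is an identifiability limit of blind 3-stain
separation, not an optimizer bug — it is the reason the
recommended workflow initializes from reference vectors and visually checks
the separation before proceeding. The acceptance script therefore reports the median of
five independent replicates.

## Background removal

The background reference `I0` is the per-channel mean of the designated
tissue-free tile (tile r0_c0 by default; the caller must designate another
tile if the first contains tissue). Each pixel gets a scalar OD (mean of the
per-channel ODs against `I0`); 10 % of the pixels of every tile are pooled
into a 46-bin histogram, and the threshold sits at the upper edge of the bin
preceding the largest drop between consecutive bin counts (ties break toward
lower OD). The rule is deliberately simple and is verified exactly against a
brute-force scan; a manual threshold overrides it for outlier slides.
Pixels below threshold become the (255,255,255) sentinel — the background is
normalized to a recognizable value, not discarded. Corrected tissue
intensities elsewhere in the pipeline are clipped to 254 so tissue can never
collide with the sentinel.

## Flat-field (vignette) correction

The radial brightness falloff of the microscope light source repeats in every
tile of a stitched slide (the mosaicking artifact). The gain surface is
estimated by pooling non-sentinel pixels of all tiles into 24×24 intra-tile
position bins: pixel intensities are first normalized by their tile's mean
(removing tile-to-tile staining differences), each bin takes a 20 % trimmed
mean, and bivariate polynomial surfaces of degree 2–4 are fitted to the
binned profile. The lowest degree wins unless a higher degree reduces the
residual by more than 20 % — raw residual ranking always prefers the most
flexible surface, which chases the spatially correlated tissue-texture noise
in the profile. The winning surface is normalized to a per-channel maximum of
1 and divided out of the non-sentinel intensities.

A fitted surface whose relative range stays below 15 % is rejected as
"uniform illumination": at realistic tile counts, weaker shading cannot be
distinguished from texture noise, so the estimator declares it uncorrectable
rather than inventing a model. On a 5×5-tile phantom with a 30 % radial
vignette the recovered gain correlates >0.99 with the generating field and
the positional intensity profile flattens to <20 % of its original
coefficient of variation.

## Detection

All detectors run on concentration channels clipped to [0, 3] (negative
values and extreme outliers carry no information about biological structure).
Components use 8-connectivity.

* **Cells (hematoxylin)** — (1) foreground at `median + k·MAD`; (2) size
  floor, then removal of the lowest 10 % (by pixel count) of intensities
  within each component; (3) mean-intensity and size ceilings; (4) per
  component, removal of the pixels most distant from the intensity-weighted
  centroid, then a size floor; (5) distance-transform watershed (seeds:
  EDT local maxima with 3 px minimum separation) with a fragment size floor.
* **Microglia (DAB)** — same skeleton, except pass 3 keeps a component iff it
  meets the size requirement *or* the intensity requirement (enough pixels
  above an intensity floor), then applies the upper size ceiling.
* **Myelin (fast blue)** — positives are the non-negative pixels strictly
  above the Wolf adaptive threshold
  `T = m − k·(1 − α·s/R)·(m − min)` computed in a 15-px window with
  reflective padding (`m`, `s`: local mean/std; `R`: global max of `s`;
  `min`: global channel minimum). `α=1` recovers the classic single-parameter
  Wolf rule; exposing `α` separately matches the two-knob parameterization
  the interactive workflow presents. A 1e-9 epsilon guards the strict
  comparison against float cancellation in perfectly flat regions.

Parameter bundles serialize to `cell_detection_parameters.json`,
`microglia_detection_parameters.json` and `myelin_detection_parameters.json`
so a reference block's parameters can be imported for further blocks.

On phantom tiles the cell detector recovers disjoint nucleus counts exactly
and the watershed separates 100 % of touching pairs placed at 1.6·radius
center distance. Single convex objects are occasionally over-split
(~5–10 % of pair-bearing tiles) by spurious EDT plateau maxima; suppressing
those (smoothing, prominence filters) was found to cost under-splitting of
genuine pairs and was not adopted.

## Density maps

Each processed 360×360 px (≈100×100 µm) small tile becomes one uniform
36×36 px block whose value is the count of the measure in that tile, so the
map's resolution roughly matches the MRI voxel grid. Cells and microglia get
a raw-count map (16-bit TIFF — counts must not clip at 255) and a
[0,255]-scaled display map (`round(255·v/max)`, half-up, zero map when all
counts are zero); myelin gets the scaled map only. Raw maps conserve the
total detection count exactly. Truncated edge tiles render as full blocks and
keep their raw counts (no area normalization), noted in the CSV sidecar.

## Registration

Histology-to-volume registration is reduced to 2D: a 4-µm section cannot
span multiple 70-µm-class MRI slices.

* **Plane and slice.** The tissue plane is the axis whose best single slice
  holds the most non-zero voxels. The best slice maximizes a similarity
  metric between the preprocessed histology overview (grayscale → min-max →
  histogram equalization → mild unsharp masking, output rescaled to [0,1])
  and each slice, with the histology resampled to the MRI grid. NMI
  (64-bin joint histogram, both-zero pixels excluded) is the default; NCC,
  SSIM and an ORB feature score (mutual nearest-neighbor matches over
  detected keypoints) populate the full score table for manual review.
* **Orientation.** The 8 dihedral operations are ranked by cosine similarity
  of HOG descriptors on a common 128² grid; HOG's unsigned gradients make the
  ranking robust to the intensity inversion between histology and MRI.
* **Affine.** 6 parameters (translation, rotation, log-scales, shear about
  the image center) optimized by Powell's method over a 3-level
  anti-aliased pyramid. The NMI and |NCC| costs are evaluated over in-view
  pixels only, with soft parameter bounds — without both, a degenerate
  shrink can correlate background with background. The HOG-ECC option runs
  the correlation optimizer on dense 3-orientation gradient-energy stacks.
  On divergence the identity is returned with a failure flag. A known
  5°/1.05×/(3,−2) px transform is recovered to <0.01 px mean corner error
  same-modality and ~0.5 px cross-modality.
* **Thin-plate splines.** Landmarks fit the backward map (MRI slice → linear
  registration output) with kernel `U(r) = r² log r`, an affine part, and
  diagonal regularization of the kernel matrix as the smoothing control
  (default 1e-6, near-interpolating; 0 interpolates exactly and reproduces
  affine-consistent landmarks with zero radial weights — both verified
  against scipy's thin-plate RBF interpolator). The O(n³) solve is capped at
  500 pairs and fewer than 30 pairs triggers a warning. Warping samples the
  source bilinearly; out-of-domain samples fall back to nearest-neighbor;
  the exported deformation field holds per-target-pixel source coordinates.
* **Mask splitting.** Candidate seeds are interior mask pixels (positive
  distance transform); unweighted k-means places `k = round(area/target)`
  centers (distance-transform-*weighted* k-means skews the catchment areas
  and breaks size balance). Regions grow synchronously, one frontier ring per
  round capped at the target size, smallest region first; leftover pixels
  attach to the nearest adjacent region, and unreachable disconnected mask
  components become their own labels. Labels partition the mask exactly and
  stay 4-connected; on a solid rectangle all subregions land within ±10 % of
  the 500-voxel default target.
* **Resampling.** Other MRI sequences are resampled onto the reference grid
  with an identity transform (SimpleITK, linear interpolation, shared-origin
  assumption), exactly matching the reference dimensions and spacing.

## Phantoms: what they emulate, and what they do not

The generators are first-class, tested code and define the validation
conditions:

* `gen_ihc_phantom` renders Beer–Lambert mixtures of the three chromogens:
  smooth tissue regions covering ~75 % of each tile (tile r0_c0 always
  empty, matching the pipeline's background assumption); a fine fibrous
  myelin texture (Gaussian-filtered noise, σ=5 px) modulated by smooth
  demyelinated lesion patches with a hard shoulder at concentration 0.12 (so
  stained tissue is separable from clean background — `lesion_severity=0`
  yields a uniformly myelinated slide); feathered nuclei discs (r=6 px,
  2-px-σ edges) and microglia ellipses (8×4 px) placed collision-free inside
  the tissue; background RGB (248,248,246) rather than pure white, so `I0`
  estimation is exercised; per-tile radial gain `1 − s·(r/R)²`; optional
  additive Gaussian OD noise. Per-small-tile object counts are recorded
  exactly.
* `gen_detection_tile` packs a known number of disjoint and deliberately
  touching (1.6·radius) objects plus an optional high-contrast myelin disc.
* `gen_mri_phantom` hides an oriented, affine-transformed, sinusoidally
  warped (invertibility-checked) and intensity-inverted copy of a histology
  template in exactly one slice of a volume; all other slices carry smooth
  decoy blobs with strictly fewer non-zero voxels.

Passing against these phantoms demonstrates the algorithms implement their
specifications and recover known ground truth under controlled noise. It does
**not** demonstrate robustness to real-tissue phenomena the generators omit:
chromogen co-localization beyond linear mixing, scattering violations of
Beer–Lambert, section tears/folds/dust, staining-batch variability, true
microglial morphology, anatomy-dependent MRI contrast, or out-of-plane
deformation (which no 2D registration can correct).

## Problem sizes

Default validation sizes were chosen so the full suite and the acceptance
script each run in a few minutes on one CPU: slide phantoms of 3×3–5×5 tiles
at 256 px (the flat-field fit needs the larger grid to average tissue texture
out of the positional profile), 360-px detection tiles, 96–128 px MRI
templates with 4–16 slices, and 30 000 sampled OD pixels for the stain fit.
Accuracy at these sizes is dominated by the effects under study, not by
sample noise, with the one documented exception of blind stain separation
above.
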