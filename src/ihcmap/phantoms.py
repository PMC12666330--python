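"""Seeded synthetic phantoms with full ground truth.

Three generators cover the whole pipeline without any real data:

* :func:`gen_ihc_phantom` — a tiled brightfield IHC slide rendered through
  the Beer-Lambert forward model from known stain vectors and concentration
  maps, with a white-ish background, per-tile radial vignetting and optional
  OD noise.  The first tile (r0, c0) contains no tissue, matching the
  pipeline's background-estimation assumption.
* :func:`gen_detection_tile` — a single concentration tile with a known
  number of feathered nuclei/microglia (optionally touching pairs) and an
  optional high-contrast myelin region.
* :func:`gen_mri_phantom` — an MRI-like volume in which exactly one slice
  holds an oriented, affine-transformed, smoothly warped and
  intensity-remapped copy of a histology template; every other slice is a
  decoy with less tissue.

All randomness flows through one seeded generator; fixed seeds give
bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .register import Affine2D, apply_orientation
from .stains import DEFAULT_STAIN_MATRIX, StainModel, pairwise_angles_deg
from .tiles import AcquisitionMetadata, TileGrid

DEFAULT_BACKGROUND_RGB = (248, 248, 246)
MIN_STAIN_ANGLE_DEG = 15.0


# ---------------------------------------------------------------------------
# IHC slide phantom
# ---------------------------------------------------------------------------


@dataclass
class IHCPhantom:
    tiles: TileGrid
    truth_M: np.ndarray
    truth_C: dict  # (r,c) -> (H,W,3) concentration maps (OD units)
    truth_background_rgb: tuple
    truth_gain: dict  # (r,c) -> (H,W) illumination gain in (0,1]
    truth_counts: dict  # 'nuclei'/'microglia' -> 2D int array over small-tile grid
    truth_objects: list  # dicts: {'class','tile','center','radius'} (tile-local centers)
    seed: int
    small_px: int
    meta: AcquisitionMetadata = field(repr=False, default=None)

    def tissue_mask(self, key) -> np.ndarray:
        return self.truth_C[key].sum(axis=-1) > 0


def _radial_gain(shape, strength: float) -> np.ndarray:
    """Per-tile vignette gain 1 - s*(r/R)^2, R = center-to-corner distance."""
    h, w = shape
    yy, xx = np.meshgrid(np.arange(h) - (h - 1) / 2, np.arange(w) - (w - 1) / 2, indexing="ij")
    r2 = yy**2 + xx**2
    return 1.0 - strength * r2 / r2.max()


def _feathered_disc(radius: float, amplitude: float, sigma: float = 2.0) -> np.ndarray:
    """Disc stamp with Gaussian-feathered edge; support trimmed below 0.02."""
    half = int(np.ceil(radius + 4 * sigma))
    yy, xx = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij")
    hard = (yy**2 + xx**2 <= radius**2).astype(float) * amplitude
    soft = ndimage.gaussian_filter(hard, sigma)
    soft[soft < 0.02] = 0.0
    return soft


def _stamp(canvas: np.ndarray, patch: np.ndarray, center):
    half = patch.shape[0] // 2
    r, c = int(round(center[0])), int(round(center[1]))
    r0, c0 = r - half, c - half
    r1, c1 = r0 + patch.shape[0], c0 + patch.shape[1]
    pr0, pc0 = max(0, -r0), max(0, -c0)
    r0, c0 = max(0, r0), max(0, c0)
    r1, c1 = min(canvas.shape[0], r1), min(canvas.shape[1], c1)
    canvas[r0:r1, c0:c1] += patch[pr0 : pr0 + (r1 - r0), pc0 : pc0 + (c1 - c0)]


def render_tile(concentrations: np.ndarray, M: np.ndarray, background_rgb,
                gain: np.ndarray | None = None, od_noise_sigma: float = 0.0,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Beer-Lambert forward rendering of a concentration map to 8-bit RGB.

    I_c = gain * I0_c * 10**(-(C M)_c), quantized by rounding.
    """
    i0 = np.asarray(background_rgb, dtype=float)
    od = concentrations @ np.asarray(M, dtype=float)
    if od_noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        od = od + rng.normal(0.0, od_noise_sigma, od.shape)
    I = i0 * np.power(10.0, -od)
    if gain is not None:
        I = I * gain[..., None]
    return np.clip(np.round(I), 0, 255).astype(np.uint8)


def _smooth_mask(shape, fraction, rng, sigma=12.0):
    """Smooth random region covering ~``fraction`` of the tile."""
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    thr = np.quantile(noise, 1.0 - fraction)
    return noise >= thr


def gen_ihc_phantom(
    seed: int = 0,
    grid=(2, 2),
    tile_px: int = 256,
    stain_matrix: np.ndarray | None = None,
    vignette_strength: float = 0.0,
    background_rgb=DEFAULT_BACKGROUND_RGB,
    tissue_fraction: float = 0.75,
    nuclei_per_tile: int = 25,
    microglia_per_tile: int = 10,
    od_noise_sigma: float = 0.0,
    small_px: int | None = None,
    pixel_size_um: float = 0.274,
    lesion_severity: float = 1.0,
) -> IHCPhantom:
    """Generate a tiled IHC slide phantom with full ground truth.

    Tile (0, 0) is pure background.  Stain rows must be pairwise separated
    by at least 15 degrees; ``vignette_strength`` in [0, 1) sets the radial
    gain falloff 1 - s*(r/R)^2 per tile.  ``tissue_fraction = 0`` produces an
    empty slide (every pixel equals the background color when vignetting and
    noise are off).  ``lesion_severity`` scales the demyelinated patches:
    1 gives fully demyelinated lesion cores, 0 a uniformly myelinated
    (normal-appearing white matter) slide.
    """
    if not (0.0 <= vignette_strength < 1.0):
        raise ValueError("vignette_strength must be in [0, 1)")
    M = DEFAULT_STAIN_MATRIX if stain_matrix is None else np.asarray(stain_matrix, dtype=float)
    model = StainModel(M)  # validates shape/condition and row-normalizes
    M = model.M
    angles = pairwise_angles_deg(M)
    if angles.min() < MIN_STAIN_ANGLE_DEG:
        raise ValueError(
            f"stain rows too collinear: min pairwise angle {angles.min():.1f} deg "
            f"< {MIN_STAIN_ANGLE_DEG} deg"
        )
    rows, cols = grid
    small_px = small_px or tile_px // 2
    if tile_px % small_px != 0:
        raise ValueError("small_px must divide tile_px")
    per = tile_px // small_px

    rng = np.random.default_rng(seed)
    gain = _radial_gain((tile_px, tile_px), vignette_strength)
    nuc_radius, mic_axes = 6.0, (8.0, 4.0)
    margin = int(nuc_radius + 10)

    tiles, truth_C, truth_gain = {}, {}, {}
    objects = []
    counts = {
        "nuclei": np.zeros((rows * per, cols * per), dtype=int),
        "microglia": np.zeros((rows * per, cols * per), dtype=int),
    }

    for R in range(rows):
        for C in range(cols):
            conc = np.zeros((tile_px, tile_px, 3))
            if (R, C) != (0, 0) and tissue_fraction > 0:
                tissue = _smooth_mask((tile_px, tile_px), tissue_fraction, rng)
                # myelin: fine fibrous texture modulated by smooth fully
                # demyelinated (lesion) patches where the concentration drops
                # to zero; unstained lesion pixels without a cell body carry
                # no chromogen at all, exactly like slide background
                fine = _unit_noise((tile_px, tile_px), rng, sigma=5.0)
                lesion = _unit_noise((tile_px, tile_px), rng, sigma=25.0)
                factor = 1.0 - lesion_severity * (1.0 - np.clip(1.9 * lesion - 0.35, 0, 1))
                myelin = (0.35 + 1.0 * fine) * factor
                # hard shoulder: staining below a visible minimum is absent,
                # so stained pixels are separable from clean background
                myelin = np.where(myelin >= 0.12, myelin, 0.0)
                conc[..., 2] = myelin * tissue
                # objects must sit fully inside tissue so truth background stays clean
                inner = ndimage.binary_erosion(tissue, iterations=margin)
                discs, nuc_centers = _place_discs(
                    inner, nuclei_per_tile, nuc_radius, rng, amp_range=(0.8, 1.2)
                )
                conc[..., 0] += discs
                conc[..., 1], mic_centers = _place_ellipses(
                    inner, microglia_per_tile, mic_axes, rng, amp=1.0,
                    avoid=nuc_centers, avoid_radius=nuc_radius,
                )
                for kind, centers, rad in (
                    ("nuclei", nuc_centers, nuc_radius),
                    ("microglia", mic_centers, max(mic_axes)),
                ):
                    for ctr in centers:
                        objects.append({"class": kind, "tile": (R, C), "center": ctr, "radius": rad})
                        sr = R * per + int(ctr[0] // small_px)
                        sc = C * per + int(ctr[1] // small_px)
                        counts[kind][sr, sc] += 1
            truth_C[(R, C)] = conc
            truth_gain[(R, C)] = gain
            tiles[(R, C)] = render_tile(
                conc, M, background_rgb, gain=gain, od_noise_sigma=od_noise_sigma, rng=rng
            )

    meta = AcquisitionMetadata(
        tile_width_px=tile_px,
        tile_height_px=tile_px,
        grid_rows=rows,
        grid_cols=cols,
        pixel_size_um=pixel_size_um,
        stain_names=model.labels,
    )
    return IHCPhantom(
        tiles=TileGrid(tiles=tiles, stage="raw"),
        truth_M=M,
        truth_C=truth_C,
        truth_background_rgb=tuple(int(v) for v in background_rgb),
        truth_gain=truth_gain,
        truth_counts=counts,
        truth_objects=objects,
        seed=seed,
        small_px=small_px,
        meta=meta,
    )


def _unit_noise(shape, rng, sigma):
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    rngv = n.max() - n.min()
    return (n - n.min()) / rngv if rngv > 0 else np.zeros(shape)


def _place_discs(allowed: np.ndarray, n: int, radius: float, rng, amp_range=(0.8, 1.2),
                 min_gap: float = 4.0):
    canvas = np.zeros(allowed.shape)
    centers: list[tuple[float, float]] = []
    cand = np.argwhere(allowed)
    if len(cand) == 0 or n == 0:
        return canvas, centers
    attempts = 0
    while len(centers) < n and attempts < 4000:
        attempts += 1
        r, c = cand[rng.integers(len(cand))]
        if all((r - pr) ** 2 + (c - pc) ** 2 >= (2 * radius + min_gap) ** 2 for pr, pc in centers):
            amp = rng.uniform(*amp_range)
            _stamp(canvas, _feathered_disc(radius, amp), (r, c))
            centers.append((float(r), float(c)))
    return canvas, centers


def _place_ellipses(allowed: np.ndarray, n: int, axes, rng, amp=0.9, min_gap: float = 6.0,
                    avoid=(), avoid_radius: float = 0.0):
    canvas = np.zeros(allowed.shape)
    centers: list[tuple[float, float]] = []
    cand = np.argwhere(allowed)
    if len(cand) == 0 or n == 0:
        return canvas, centers
    a, b = axes
    half = int(np.ceil(a + 8))
    yy, xx = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij")
    sep = 2 * a + min_gap
    avoid_sep = a + avoid_radius + min_gap
    attempts = 0
    while len(centers) < n and attempts < 4000:
        attempts += 1
        r, c = cand[rng.integers(len(cand))]
        if not all((r - pr) ** 2 + (c - pc) ** 2 >= sep**2 for pr, pc in centers):
            continue
        if avoid and not all(
            (r - pr) ** 2 + (c - pc) ** 2 >= avoid_sep**2 for pr, pc in avoid
        ):
            continue
        th = rng.uniform(0, np.pi)
        u = yy * np.cos(th) + xx * np.sin(th)
        v = -yy * np.sin(th) + xx * np.cos(th)
        hard = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float) * amp
        patch = ndimage.gaussian_filter(hard, 2.0)
        patch[patch < 0.02] = 0.0
        _stamp(canvas, patch, (r, c))
        centers.append((float(r), float(c)))
    return canvas, centers


# ---------------------------------------------------------------------------
# Detection tile phantom
# ---------------------------------------------------------------------------


def gen_detection_tile(
    seed: int = 0,
    n_nuclei: int = 20,
    n_microglia: int = 0,
    overlap_pairs: int = 0,
    tile_px: int = 360,
    radius: float = 6.0,
    myelin_blob: bool = False,
):
    """Single concentration tile with known object layout.

    Returns ``(conc, truth)`` where ``conc`` is (H, W, 3) float
    (channels: hematoxylin nuclei, DAB microglia, myelin) and ``truth``
    lists centers, per-object hard-disc areas, per-class counts and the
    merged (touching) pairs.  ``overlap_pairs`` pairs of nuclei are placed
    with center distance 1.6*radius (< 2*radius); all other objects are
    pairwise disjoint with >= 2 px gaps.
    """
    if overlap_pairs > n_nuclei // 2:
        raise ValueError("overlap_pairs must be <= n_nuclei/2")
    rng = np.random.default_rng(seed)
    conc = np.zeros((tile_px, tile_px, 3))
    margin = int(radius + 12)
    if tile_px <= 2 * margin:
        raise ValueError("objects do not fit in the tile")

    sep = 2 * radius + 4.0  # guarantees feathered supports stay disjoint
    centers: list[tuple[float, float]] = []
    merged: list[tuple[int, int]] = []

    def fits(pt, exempt=()):
        return all(
            (pt[0] - q[0]) ** 2 + (pt[1] - q[1]) ** 2 >= sep**2
            for i, q in enumerate(centers)
            if i not in exempt
        )

    def sample_pt():
        return (
            float(rng.uniform(margin, tile_px - margin)),
            float(rng.uniform(margin, tile_px - margin)),
        )

    # touching pairs first (each consumes two nuclei)
    attempts = 0
    while len(merged) < overlap_pairs:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("infeasible packing: cannot place overlapping pairs")
        p = sample_pt()
        th = rng.uniform(0, 2 * np.pi)
        q = (p[0] + 1.6 * radius * np.sin(th), p[1] + 1.6 * radius * np.cos(th))
        if not (margin <= q[0] <= tile_px - margin and margin <= q[1] <= tile_px - margin):
            continue
        if fits(p) and fits(q):
            i, j = len(centers), len(centers) + 1
            centers.extend([p, q])
            merged.append((i, j))

    while len(centers) < n_nuclei:
        attempts += 1
        if attempts > 40000:
            raise RuntimeError("infeasible packing: cannot place disjoint nuclei")
        p = sample_pt()
        if fits(p):
            centers.append(p)

    disc_area = int(np.sum(_feathered_disc(radius, 1.0, sigma=0.01) > 0.5))
    for ctr in centers:
        _stamp(conc[..., 0], _feathered_disc(radius, 1.0), ctr)

    mic_centers: list[tuple[float, float]] = []
    a, b = 8.0, 4.0
    while len(mic_centers) < n_microglia:
        attempts += 1
        if attempts > 60000:
            raise RuntimeError("infeasible packing: cannot place microglia")
        p = sample_pt()
        ok = all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= (2 * a + 4) ** 2 for q in mic_centers)
        ok = ok and fits(p)
        if ok:
            mic_centers.append(p)
    half = int(np.ceil(a + 8))
    yy, xx = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij")
    for ctr in mic_centers:
        th = rng.uniform(0, np.pi)
        u = yy * np.cos(th) + xx * np.sin(th)
        v = -yy * np.sin(th) + xx * np.cos(th)
        hard = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float) * 0.9
        patch = ndimage.gaussian_filter(hard, 2.0)
        patch[patch < 0.02] = 0.0
        _stamp(conc[..., 1], patch, ctr)

    myelin_mask = np.zeros((tile_px, tile_px), dtype=bool)
    if myelin_blob:
        yy2, xx2 = np.meshgrid(np.arange(tile_px), np.arange(tile_px), indexing="ij")
        cy, cx = tile_px * 0.45, tile_px * 0.55
        myelin_mask = (yy2 - cy) ** 2 + (xx2 - cx) ** 2 <= (tile_px / 3.0) ** 2
        conc[..., 2][myelin_mask] = 1.5

    truth = {
        "nuclei_centers": centers,
        "microglia_centers": mic_centers,
        "merged_pairs": merged,
        "counts": {"nuclei": len(centers), "microglia": len(mic_centers)},
        "disc_area_px": disc_area,
        "radius": radius,
        "myelin_mask": myelin_mask,
    }
    return conc, truth


# ---------------------------------------------------------------------------
# MRI phantom
# ---------------------------------------------------------------------------


@dataclass
class MRIPhantom:
    volume: np.ndarray
    spacing: tuple
    truth_plane: int
    truth_slice: int
    truth_orientation: int
    truth_affine: Affine2D
    truth_warp: np.ndarray  # (H,W,2) per-target-pixel backward displacement
    template: np.ndarray
    oriented: np.ndarray = field(repr=False, default=None)
    affined: np.ndarray = field(repr=False, default=None)
    truth_slice_image: np.ndarray = field(repr=False, default=None)
    seed: int = 0

    def nifti(self) -> "nib.Nifti1Image":
        import nibabel as nib

        img = nib.Nifti1Image(self.volume.astype(np.float32), np.diag(list(self.spacing) + [1.0]))
        img.header.set_zooms(self.spacing)
        return img


def make_histology_template(seed: int = 0, size: int = 96) -> np.ndarray:
    """Asymmetric textured tissue-like 2D template in [0, 1] on a zero background."""
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.linspace(-1, 1, size), np.linspace(-1, 1, size), indexing="ij")
    body = ((yy + 0.05) / 0.75) ** 2 + ((xx - 0.05) / 0.6) ** 2 <= 1.0
    notch = ((yy - 0.35) / 0.28) ** 2 + ((xx - 0.38) / 0.2) ** 2 <= 1.0
    lobe = ((yy + 0.45) / 0.22) ** 2 + ((xx + 0.32) / 0.33) ** 2 <= 1.0
    mask = (body & ~notch) | lobe
    texture = 0.45 + 0.5 * _unit_noise((size, size), rng, sigma=4.0)
    streak = 0.2 * np.sin(6.0 * (yy + 0.8 * xx))
    tpl = np.clip((texture + streak), 0.05, 1.0) * mask
    return tpl


def _warp_displacement(shape, amplitude: float, wavelength: float, rng) -> np.ndarray:
    h, w = shape
    ph = rng.uniform(0, 2 * np.pi, size=2)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dr = amplitude * np.sin(2 * np.pi * cc / wavelength + ph[0])
    dc = amplitude * np.cos(2 * np.pi * rr / wavelength + ph[1])
    return np.stack([dr, dc], axis=-1)


def _check_invertible(disp: np.ndarray):
    dr_dy, dr_dx = np.gradient(disp[..., 0])
    dc_dy, dc_dx = np.gradient(disp[..., 1])
    det = (1 + dr_dy) * (1 + dc_dx) - dr_dx * dc_dy
    if det.min() <= 0:
        raise ValueError(
            f"warp amplitude folds the domain (min Jacobian {det.min():.3f} <= 0)"
        )


def gen_mri_phantom(
    histology_template: np.ndarray,
    n_slices: int = 16,
    truth_slice: int = 7,
    affine_params: Affine2D | None = None,
    warp_amplitude: float = 0.0,
    seed: int = 0,
    plane_axis: int = 0,
    orientation: int = 0,
    warp_wavelength: float = 48.0,
    noise_sigma: float = 0.0,
    spacing=(0.4, 0.13, 0.13),
) -> MRIPhantom:
    """MRI-like volume whose slice ``truth_slice`` hides the histology template.

    The template is oriented (dihedral op), affine-transformed, warped by a
    smooth sinusoidal backward displacement field, intensity-inverted to an
    MRI-like contrast, and stacked with smooth decoy blobs (strictly fewer
    non-zero voxels) on every other slice.
    """
    tpl = np.asarray(histology_template, dtype=float)
    if not 0 <= truth_slice < n_slices:
        raise ValueError("truth_slice out of range")
    rng = np.random.default_rng(seed)
    h, w = tpl.shape
    affine = affine_params or Affine2D.identity()

    oriented = apply_orientation(tpl, orientation)
    if oriented.shape != tpl.shape:  # non-square templates change shape under rot90
        from skimage.transform import resize

        oriented = resize(oriented, tpl.shape, preserve_range=True, anti_aliasing=True)
    affined = affine.warp(oriented, output_shape=(h, w))
    support_aff = affine.warp((apply_orientation(tpl, orientation) > 0).astype(float),
                              output_shape=(h, w)) > 0.5

    disp = _warp_displacement((h, w), warp_amplitude, warp_wavelength, rng)
    if warp_amplitude > 0:
        _check_invertible(disp)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    src_r, src_c = rr + disp[..., 0], cc + disp[..., 1]
    warped = ndimage.map_coordinates(affined, [src_r.ravel(), src_c.ravel()], order=1).reshape(h, w)
    support = (
        ndimage.map_coordinates(support_aff.astype(float), [src_r.ravel(), src_c.ravel()], order=1)
        .reshape(h, w)
        > 0.5
    )

    truth_img = np.where(support, 0.25 + 0.75 * (1.0 - warped), 0.0)
    if noise_sigma > 0:
        truth_img = np.where(
            support, np.clip(truth_img + rng.normal(0, noise_sigma, truth_img.shape), 0.05, 1.2), 0.0
        )

    truth_area = int(support.sum())
    slices = []
    for i in range(n_slices):
        if i == truth_slice:
            slices.append(truth_img)
            continue
        blob = _smooth_mask((h, w), max(0.05, 0.55 * truth_area / (h * w)), rng, sigma=9.0)
        # decoys must hold strictly fewer non-zero voxels than the truth slice
        if blob.sum() >= truth_area:
            keep = np.argwhere(blob)
            rng.shuffle(keep)
            drop = keep[: blob.sum() - truth_area + 1 + truth_area // 10]
            blob[drop[:, 0], drop[:, 1]] = False
        vals = (0.3 + 0.6 * _unit_noise((h, w), rng, sigma=6.0)) * blob
        slices.append(vals)

    volume = np.stack(slices, axis=plane_axis)
    return MRIPhantom(
        volume=volume,
        spacing=tuple(spacing),
        truth_plane=plane_axis,
        truth_slice=truth_slice,
        truth_orientation=orientation,
        truth_affine=affine,
        truth_warp=disp,
        template=tpl,
        oriented=oriented,
        affined=affined,
        truth_slice_image=truth_img,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Disk export in the pipeline layout
# ---------------------------------------------------------------------------


def write_ihc_phantom(phantom: IHCPhantom, directory) -> None:
    """Write tiles, metadata and ground truth in the layout the pipeline reads."""
    import json
    from pathlib import Path

    directory = Path(directory)
    (directory / "Data").mkdir(parents=True, exist_ok=True)
    phantom.tiles.save(directory / "Data" / "Tiles-Medium")
    (directory / "Parameters").mkdir(exist_ok=True)
    phantom.meta.to_csv(directory / "Parameters" / "Metadata.csv")
    np.savez_compressed(
        directory / "ground_truth.npz",
        truth_M=phantom.truth_M,
        counts_nuclei=phantom.truth_counts["nuclei"],
        counts_microglia=phantom.truth_counts["microglia"],
        **{f"gain_r{r}_c{c}": g for (r, c), g in phantom.truth_gain.items()},
    )
    (directory / "ground_truth.json").write_text(
        json.dumps(
            {
                "seed": phantom.seed,
                "background_rgb": phantom.truth_background_rgb,
                "small_px": phantom.small_px,
                "objects": [
                    {**o, "center": list(o["center"])} for o in phantom.truth_objects
                ],
            },
            indent=2,
        )
    )
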