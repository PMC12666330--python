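"""Luminance normalization, OD background removal, flat-field correction.

Background separation works on a scalar per-pixel optical density (mean of
the per-channel ODs against the background reference I0, estimated from the
tissue-free first tile).  White-ish background pixels cluster at low OD; the
threshold sits at the largest frequency drop between consecutive bins of the
global OD histogram (46 bins by default).  Background pixels become the
(255,255,255) sentinel and stay excluded from every later statistic.

The mosaicking (vignette) artifact is corrected by a per-channel gain
surface over intra-tile position, fitted to position-binned robust means of
the non-sentinel pixels pooled across all tiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stains import rgb_to_od, sentinel_mask
from .tiles import TileGrid

DEFAULT_BINS = 46
DEFAULT_SAMPLE_FRACTION = 0.10


# ---------------------------------------------------------------------------
# L-channel normalization
# ---------------------------------------------------------------------------


def normalize_l_channel(grid: TileGrid) -> TileGrid:
    """Global min-max normalization of the CIELAB L channel across the grid.

    All tiles are converted RGB -> CIELAB, the L channel is rescaled by the
    grid-global minimum and maximum to the full [0, 100] range (a and b are
    untouched), and converted back to RGB with clipping.  A grid whose L is
    globally constant is returned unchanged with a warning.
    """
    from skimage import color

    labs = {k: color.rgb2lab(t / 255.0) for k, t in grid.tiles.items()}
    lmin = min(float(l[..., 0].min()) for l in labs.values())
    lmax = max(float(l[..., 0].max()) for l in labs.values())
    if lmax - lmin < 1e-9:
        warnings.warn("global L channel is constant; normalization is a no-op")
        return TileGrid(tiles=dict(grid.tiles), stage="Lnorm", truncated=grid.truncated)
    out = {}
    for k, lab in labs.items():
        lab = lab.copy()
        lab[..., 0] = (lab[..., 0] - lmin) / (lmax - lmin) * 100.0
        rgb = np.clip(np.round(color.lab2rgb(lab) * 255.0), 0, 255).astype(np.uint8)
        out[k] = rgb
    return TileGrid(tiles=out, stage="Lnorm", truncated=grid.truncated)


# ---------------------------------------------------------------------------
# Background model
# ---------------------------------------------------------------------------


@dataclass
class BackgroundModel:
    I0: tuple                    # background reference RGB (from the tissue-free tile)
    od_threshold: float
    bin_edges: np.ndarray = field(repr=False, default=None)
    counts: np.ndarray = field(repr=False, default=None)
    bins: int = DEFAULT_BINS
    manual: bool = False

    def __post_init__(self):
        if self.od_threshold < 0:
            raise ValueError("od_threshold must be >= 0")
        if any(not (1 <= v <= 255) for v in self.I0):
            raise ValueError("I0 components must be in [1, 255]")


def scalar_od(tile: np.ndarray, i0) -> np.ndarray:
    """Channel-mean optical density of each pixel against I0."""
    return rgb_to_od(tile, i0).mean(axis=-1)


def largest_drop_threshold(counts: np.ndarray, bin_edges: np.ndarray) -> float:
    """Threshold at the upper edge of the bin preceding the largest
    consecutive-bin count drop; ties break toward lower OD."""
    drops = counts[:-1].astype(np.int64) - counts[1:].astype(np.int64)
    i = int(np.argmax(drops))  # argmax takes the first (lowest-OD) maximum
    return float(bin_edges[i + 1])


def estimate_background(
    grid: TileGrid,
    bins: int = DEFAULT_BINS,
    sample_fraction: float = DEFAULT_SAMPLE_FRACTION,
    manual_threshold: float | None = None,
    background_tile=(0, 0),
    seed: int = 0,
    systematic: bool = False,
) -> BackgroundModel:
    """Estimate I0 and the OD background threshold from a tile grid.

    I0 is the per-channel average of the designated background tile (the
    first tile by default; the caller must point elsewhere if it contains
    tissue).  10% of the pixels of every tile are sampled into a global OD
    histogram and the threshold is placed after its largest frequency drop.
    ``manual_threshold`` overrides the histogram estimate entirely.
    ``systematic`` switches from seeded random sampling to a deterministic
    per-tile stride.
    """
    if background_tile not in grid.tiles:
        raise ValueError(f"background tile {background_tile} not present in grid")
    bg = grid.tiles[background_tile].astype(float)
    I0 = tuple(float(np.clip(bg[..., c].mean(), 1, 255)) for c in range(3))

    rng = np.random.default_rng(seed)
    samples = []
    for key in sorted(grid.tiles):
        od = scalar_od(grid.tiles[key], I0).ravel()
        n = od.size
        take = max(1, int(round(sample_fraction * n)))
        if systematic:
            idx = np.arange(0, n, max(1, n // take))[:take]
        else:
            idx = rng.choice(n, take, replace=False)
        samples.append(od[idx])
    pooled = np.concatenate(samples)

    if manual_threshold is not None:
        counts, edges = np.histogram(pooled, bins=bins)
        return BackgroundModel(I0=I0, od_threshold=float(manual_threshold),
                               bin_edges=edges, counts=counts, bins=bins, manual=True)
    if np.ptp(pooled) < 1e-12:
        raise ValueError("cannot estimate threshold: all sampled OD values identical")
    counts, edges = np.histogram(pooled, bins=bins)
    thr = largest_drop_threshold(counts, edges)
    return BackgroundModel(I0=I0, od_threshold=thr, bin_edges=edges, counts=counts, bins=bins)


def remove_background(grid: TileGrid, model: BackgroundModel) -> TileGrid:
    """Set pixels with scalar OD below the threshold to the (255,255,255) sentinel."""

    def _clean(tile):
        od = scalar_od(tile, model.I0)
        out = tile.copy()
        out[od < model.od_threshold] = 255
        return out

    return grid.map_tiles(_clean, stage="bgremoved")


def plot_od_histogram(model: BackgroundModel, path) -> None:
    """Write the OD-Histogram.png diagnostic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    widths = np.diff(model.bin_edges)
    ax.bar(model.bin_edges[:-1], model.counts, width=widths, align="edge",
           alpha=0.7, color="steelblue")
    ax.axvline(model.od_threshold, color="crimson", ls="--",
               label=f"threshold = {model.od_threshold:.3f}")
    ax.set_xlabel("optical density")
    ax.set_ylabel("sampled pixel count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Flat-field model
# ---------------------------------------------------------------------------


@dataclass
class FlatFieldModel:
    """Separable per-channel polynomial gain over intra-tile position.

    ``gain`` holds the full-resolution (tile_h, tile_w, 3) surface with a
    per-channel maximum of 1; ``diagnostics`` records candidate degrees,
    their residuals and any uniform-profile rejections.
    """

    gain: np.ndarray
    degree: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.gain <= 0):
            raise ValueError("gain surface must be strictly positive")


def _poly_terms(y: np.ndarray, x: np.ndarray, degree: int) -> np.ndarray:
    cols = [np.ones_like(y)]
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            if i == 0 and j == 0:
                continue
            cols.append((y**i) * (x**j))
    return np.stack(cols, axis=-1)


def estimate_flat_field(
    grid: TileGrid,
    position_bins: int = 24,
    degrees=(2, 3, 4),
    uniform_tol: float = 0.15,
    trim: float = 0.2,
    parsimony_ratio: float = 0.8,
) -> FlatFieldModel:
    """Fit the illumination gain surface from a background-removed grid.

    Non-sentinel pixels of all tiles are normalized by their tile's mean
    intensity (removing tile-to-tile staining differences) and pooled into
    ``position_bins``^2 intra-tile position bins; per-bin per-channel
    trimmed means form the intensity profile.  Bivariate polynomial
    surfaces of the candidate degrees are fitted to the profile; the lowest
    degree wins unless a higher one cuts the residual below
    ``parsimony_ratio`` times the current best (higher degrees chase the
    spatially correlated tissue-texture noise otherwise).  A fitted surface
    whose relative range stays below ``uniform_tol`` is indistinguishable
    from texture noise and is rejected as artificially uniform; shading
    weaker than that floor is declared uncorrectable.  The winning surface
    is normalized to a per-channel maximum of 1.
    """
    from scipy import stats

    th, tw, _ = grid.tile_shape
    nb = position_bins
    flats, values = [], []
    for tile in grid.tiles.values():
        if tile.shape[:2] != (th, tw):
            continue
        keep = ~sentinel_mask(tile)
        if not keep.any():
            continue
        ys, xs = np.nonzero(keep)
        vals = tile[ys, xs].astype(float)
        vals = vals / np.clip(vals.mean(axis=0, keepdims=True), 1e-9, None)
        flats.append((ys * nb) // th * nb + (xs * nb) // tw)
        values.append(vals)
    if not flats:
        raise ValueError("no non-sentinel pixels; cannot estimate flat field")
    flat = np.concatenate(flats)
    vals = np.concatenate(values)
    order = np.argsort(flat, kind="stable")
    flat_s, vals_s = flat[order], vals[order]
    bounds = np.searchsorted(flat_s, np.arange(nb * nb + 1))
    profile = np.full((nb * nb, 3), np.nan)
    for b in range(nb * nb):
        lo, hi = bounds[b], bounds[b + 1]
        if hi - lo > 20:
            profile[b] = stats.trim_mean(vals_s[lo:hi], trim, axis=0)
    valid = ~np.isnan(profile[:, 0])
    if valid.sum() < 12:
        raise ValueError("too few populated position bins; cannot estimate flat field")

    rel_range = [float(np.ptp(profile[valid, c]) / max(profile[valid, c].mean(), 1e-9))
                 for c in range(3)]

    by, bx = np.divmod(np.arange(nb * nb)[valid], nb)
    yc = (by + 0.5) / nb
    xc = (bx + 0.5) / nb
    results = {}
    best = None
    for deg in sorted(degrees):
        T = _poly_terms(yc, xc, deg)
        resid = 0.0
        coefs = []
        for c in range(3):
            coef, *_ = np.linalg.lstsq(T, profile[valid, c], rcond=None)
            coefs.append(coef)
            resid += float(np.sum((T @ coef - profile[valid, c]) ** 2))
        results[deg] = resid
        if best is None or resid < parsimony_ratio * best[1]:
            best = (deg, resid, coefs)
    deg, resid, coefs = best

    yy, xx = np.meshgrid((np.arange(th) + 0.5) / th, (np.arange(tw) + 0.5) / tw, indexing="ij")
    T_full = _poly_terms(yy.ravel(), xx.ravel(), deg)
    gain = np.stack([(T_full @ coefs[c]).reshape(th, tw) for c in range(3)], axis=-1)
    gain = np.clip(gain, 1e-6, None)
    gain = gain / gain.reshape(-1, 3).max(axis=0)
    fitted_range = float((gain.max() - gain.min()) / gain.mean())
    if fitted_range < uniform_tol:
        raise ValueError(
            "uniform illumination, nothing to correct "
            f"(fitted gain range {fitted_range:.3f} below {uniform_tol})"
        )
    return FlatFieldModel(
        gain=gain,
        degree=deg,
        diagnostics={
            "candidate_residuals": results,
            "channel_rel_range": rel_range,
            "uniform_rejected": [r < uniform_tol for r in rel_range],
        },
    )


def positional_intensity_cv(grid: TileGrid, position_bins: int = 6, trim: float = 0.2) -> float:
    """Coefficient of variation of the intra-tile positional intensity profile.

    The profile is the per-position-bin trimmed mean of tile-normalized
    non-sentinel intensities pooled across tiles — the mosaicking artifact's
    signature.  A vignette-free, well-corrected grid has a flat profile
    (CV near 0); the ratio of this statistic after/before correction
    quantifies how much of the artifact was removed.
    """
    from scipy import stats

    th, tw, _ = grid.tile_shape
    nb = position_bins
    flats, values = [], []
    for tile in grid.tiles.values():
        if tile.shape[:2] != (th, tw):
            continue
        keep = ~sentinel_mask(tile)
        if not keep.any():
            continue
        ys, xs = np.nonzero(keep)
        v = tile[ys, xs].astype(float).mean(axis=1)
        v = v / max(v.mean(), 1e-9)
        flats.append((ys * nb) // th * nb + (xs * nb) // tw)
        values.append(v)
    if not flats:
        raise ValueError("no non-sentinel pixels")
    flat = np.concatenate(flats)
    vals = np.concatenate(values)
    order = np.argsort(flat, kind="stable")
    flat_s, vals_s = flat[order], vals[order]
    bounds = np.searchsorted(flat_s, np.arange(nb * nb + 1))
    prof = []
    for b in range(nb * nb):
        lo, hi = bounds[b], bounds[b + 1]
        if hi - lo > 20:
            prof.append(stats.trim_mean(vals_s[lo:hi], trim))
    prof = np.asarray(prof)
    return float(prof.std() / max(prof.mean(), 1e-9))


def apply_flat_field(grid: TileGrid, model: FlatFieldModel) -> TileGrid:
    """Divide non-sentinel pixels by the gain surface (sentinels pass through).

    Corrected intensities are clipped to [0, 254] so tissue can never
    collide with the background sentinel value.
    """
    th, tw, _ = grid.tile_shape
    if model.gain.shape[:2] != (th, tw):
        raise ValueError("flat-field model does not match tile dimensions")
    if np.any(model.gain <= 0):
        raise ValueError("gain must be strictly positive")

    def _correct(tile):
        out = tile.astype(float)
        sm = sentinel_mask(tile)
        if tile.shape[:2] == (th, tw):
            corrected = np.clip(out / model.gain, 0, 254)
            out = np.where(sm[..., None], out, corrected)
        return np.round(out).astype(np.uint8)

    return grid.map_tiles(_correct, stage="illumcorrected")
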