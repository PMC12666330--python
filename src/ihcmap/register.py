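"""Histology-to-MRI registration: slice matching, 2D affine, thin-plate splines.

The 2D-to-3D problem is reduced to 2D-to-2D: the anatomical plane of the
tissue block is the one whose best slice holds the most non-zero voxels, the
best slice is found by a similarity metric (NMI by default), the in-plane
orientation is ranked by HOG similarity over the 8 dihedral operations, a
6-dof affine gives coarse alignment, and landmark thin-plate splines refine
it.  All 2D coordinates are (row, col), 0-based, at pixel centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

# ---------------------------------------------------------------------------
# Orientation ops (dihedral group of the square)
# ---------------------------------------------------------------------------

N_ORIENTATIONS = 8


def apply_orientation(image: np.ndarray, op: int) -> np.ndarray:
    """Apply dihedral op 0..7: rot90 by (op % 4), then left-right flip if op >= 4."""
    if not 0 <= op < N_ORIENTATIONS:
        raise ValueError("orientation op must be in 0..7")
    out = np.rot90(image, k=op % 4)
    if op >= 4:
        out = np.fliplr(out)
    return np.ascontiguousarray(out)


def invert_orientation(op: int) -> int:
    """The op that undoes ``op`` (flips are involutions; rotations negate)."""
    if op < 4:
        return (-op) % 4
    return op  # flip-then-rotate ops are self-inverse under this composition


# ---------------------------------------------------------------------------
# 2D affine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Affine2D:
    """6-dof 2D affine mapping source (r, c) to target (r, c): p_t = A p_s + t."""

    matrix: np.ndarray  # 2x3
    method: str = "identity"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, method: str = "identity") -> "Affine2D":
        return cls(np.hstack([np.eye(2), np.zeros((2, 1))]), method=method)

    @classmethod
    def from_params(
        cls,
        rotation_deg: float = 0.0,
        scale=(1.0, 1.0),
        shear: float = 0.0,
        translation=(0.0, 0.0),
        center=(0.0, 0.0),
        method: str = "params",
    ) -> "Affine2D":
        """Rotation/scale/shear about ``center`` followed by translation."""
        th = np.deg2rad(rotation_deg)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        S = np.diag(scale)
        H = np.array([[1.0, shear], [0.0, 1.0]])
        A = R @ S @ H
        ctr = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float) + ctr - A @ ctr
        return cls(np.hstack([A, t[:, None]]), method=method)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "Affine2D":
        A = self.matrix[:, :2]
        Ai = np.linalg.inv(A)
        return Affine2D(np.hstack([Ai, (-Ai @ self.matrix[:, 2])[:, None]]), method=self.method)

    def warp(self, image: np.ndarray, output_shape=None, order: int = 1, cval: float = 0.0) -> np.ndarray:
        """Resample ``image`` (source) onto the target grid."""
        if output_shape is None:
            output_shape = image.shape[:2]
        rr, cc = np.meshgrid(np.arange(output_shape[0]), np.arange(output_shape[1]), indexing="ij")
        tgt = np.stack([rr.ravel(), cc.ravel()], axis=1)
        src = self.inverse().apply_points(tgt)
        out = ndimage.map_coordinates(
            np.asarray(image, dtype=float), [src[:, 0], src[:, 1]], order=order, cval=cval
        )
        return out.reshape(output_shape)


# ---------------------------------------------------------------------------
# NIfTI plumbing
# ---------------------------------------------------------------------------

_LUMA = np.array([0.299, 0.587, 0.114])  # Rec. 601


def to_grayscale(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return image[..., :3] @ _LUMA
    return image


def image_to_slice_nifti(image: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> nib.Nifti1Image:
    """Wrap a 2D image as a single-slice NIfTI volume with declared spacing."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    gray = to_grayscale(image)
    vol = gray[:, :, None].astype(np.float32)
    affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms(spacing_mm)
    return img


# ---------------------------------------------------------------------------
# Preprocessing and similarity metrics
# ---------------------------------------------------------------------------


def preprocess_for_registration(image: np.ndarray) -> np.ndarray:
    """Grayscale -> min-max normalize -> histogram equalize -> edge-enhance.

    Output is in [0, 1].  A constant image is returned unchanged with a
    warning (equalization is skipped).
    """
    from skimage import exposure, filters

    g = to_grayscale(image).astype(float)
    lo, hi = g.min(), g.max()
    if hi - lo < 1e-12:
        warnings.warn("constant image: skipping normalization/equalization")
        return g
    g = (g - lo) / (hi - lo)
    g = exposure.equalize_hist(g)
    # mild unsharp masking: strong enhancement re-ranks the histogram and
    # destroys the near-idempotency of the chain
    sharp = np.clip(g + 0.1 * (g - filters.gaussian(g, sigma=2)), 0.0, 1.0)
    lo, hi = sharp.min(), sharp.max()
    return (sharp - lo) / (hi - lo) if hi > lo else sharp


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def normalized_mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 64,
                                  exclude_background: bool = True) -> float:
    """NMI = (H(a)+H(b))/H(a,b) over a joint histogram (64 bins by default).

    Pixels that are zero in BOTH images are excluded when
    ``exclude_background`` (black background dominates tissue-block images).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if exclude_background:
        keep = (a != 0) | (b != 0)
        if keep.sum() < 16:
            warnings.warn("degenerate NMI input; returning floor 1.0")
            return 1.0
        a, b = a[keep], b[keep]
    if a.max() - a.min() < 1e-12 or b.max() - b.min() < 1e-12:
        warnings.warn("constant NMI input; returning floor 1.0")
        return 1.0
    h, _, _ = np.histogram2d(a, b, bins=bins)
    pxy = h / h.sum()
    hx = _entropy(pxy.sum(axis=1))
    hy = _entropy(pxy.sum(axis=0))
    hxy = _entropy(pxy.ravel())
    if hxy <= 0:
        warnings.warn("degenerate joint entropy; returning floor 1.0")
        return 1.0
    return (hx + hy) / hxy


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        warnings.warn("constant NCC input; returning floor 0.0")
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _ssim(a: np.ndarray, b: np.ndarray) -> float:
    from skimage.metrics import structural_similarity

    def norm(x):
        x = np.asarray(x, dtype=float)
        rng = x.max() - x.min()
        return (x - x.min()) / rng if rng > 1e-12 else np.zeros_like(x)

    if (np.ptp(a) < 1e-12) or (np.ptp(b) < 1e-12):
        warnings.warn("constant SSIM input; returning floor 0.0")
        return 0.0
    return float(structural_similarity(norm(a), norm(b), data_range=1.0))


def _feature_score(a: np.ndarray, b: np.ndarray) -> float:
    """ORB mutual nearest-neighbor matches normalized by keypoint count."""
    from skimage.feature import ORB, match_descriptors

    def detect(img):
        img = np.asarray(img, dtype=float)
        rng = img.max() - img.min()
        img = (img - img.min()) / rng if rng > 1e-12 else img
        orb = ORB(n_keypoints=200, fast_threshold=0.05)
        try:
            orb.detect_and_extract(img)
        except RuntimeError:
            return None
        return orb.descriptors

    da, db = detect(a), detect(b)
    if da is None or db is None or len(da) == 0 or len(db) == 0:
        warnings.warn("no ORB keypoints; feature score floor 0.0")
        return 0.0
    matches = match_descriptors(da, db, cross_check=True, max_ratio=0.9)
    return len(matches) / max(1, min(len(da), len(db)))


_METRICS = {
    "nmi": normalized_mutual_information,
    "ncc": normalized_cross_correlation,
    "ssim": _ssim,
    "feature": _feature_score,
}


def score_slice(hist: np.ndarray, mri_slice: np.ndarray, metric: str = "nmi") -> float:
    """Similarity between a preprocessed histology image and one MRI slice.

    Higher is more similar for all four metrics.  The histology image is
    resampled to the (coarser) MRI slice grid for comparison.
    """
    from skimage.transform import resize

    metric = metric.lower()
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRICS)}")
    h = np.asarray(hist, dtype=float)
    s = np.asarray(mri_slice, dtype=float)
    if h.shape != s.shape:
        h = resize(h, s.shape, preserve_range=True, anti_aliasing=True)
    return _METRICS[metric](h, s)


# ---------------------------------------------------------------------------
# Plane / slice / orientation selection
# ---------------------------------------------------------------------------


def find_plane(volume: np.ndarray) -> int:
    """Axis whose single best slice contains the most non-zero voxels."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    if not np.any(volume):
        raise ValueError("all-zero volume")
    best = [
        max(np.count_nonzero(np.take(volume, i, axis=ax)) for i in range(volume.shape[ax]))
        for ax in range(3)
    ]
    return int(np.argmax(best))  # ties -> lowest axis


@dataclass
class SliceMatch:
    plane_axis: int
    slice_index: int
    orientation: int | None
    scores: "object"  # pandas DataFrame: one row per slice, one column per metric
    metric: str


def find_best_slice(
    volume: np.ndarray,
    hist: np.ndarray,
    metric: str = "nmi",
    plane_axis: int | None = None,
    all_metrics: bool = True,
) -> SliceMatch:
    """Argmax of the chosen metric over the slices of the tissue plane.

    The full per-slice score table (all four metrics when ``all_metrics``)
    is retained so a manual-selection report can print them.
    """
    import pandas as pd

    volume = np.asarray(volume, dtype=float)
    axis = find_plane(volume) if plane_axis is None else plane_axis
    names = list(_METRICS) if all_metrics else [metric.lower()]
    rows = []
    for i in range(volume.shape[axis]):
        sl = np.take(volume, i, axis=axis)
        rows.append({m: score_slice(hist, sl, m) for m in names})
    table = pd.DataFrame(rows)
    col = table[metric.lower()].to_numpy()
    if np.ptp(col) < 1e-12:
        warnings.warn("all slices score identically; returning the lowest index")
    idx = int(np.argmax(col))
    return SliceMatch(plane_axis=axis, slice_index=idx, orientation=None, scores=table, metric=metric.lower())


def rank_orientations(hist: np.ndarray, mri_slice: np.ndarray, grid: int = 128):
    """Rank the 8 dihedral orientations of ``hist`` by HOG similarity to the slice.

    Returns a list of (op, score) sorted by descending score; equal scores
    keep ascending op order (stable).
    """
    from skimage.feature import hog
    from skimage.transform import resize

    def feats(img):
        img = np.asarray(img, dtype=float)
        rng = img.max() - img.min()
        img = (img - img.min()) / rng if rng > 1e-12 else img
        img = resize(img, (grid, grid), preserve_range=True, anti_aliasing=True)
        return hog(img, orientations=9, pixels_per_cell=(16, 16), cells_per_block=(2, 2))

    ref = feats(mri_slice)
    scores = []
    for op in range(N_ORIENTATIONS):
        f = feats(apply_orientation(hist, op))
        denom = np.linalg.norm(f) * np.linalg.norm(ref)
        scores.append((op, float(f @ ref / denom) if denom > 1e-12 else 0.0))
    return sorted(scores, key=lambda t: (-t[1], t[0]))


# ---------------------------------------------------------------------------
# Linear (affine) registration
# ---------------------------------------------------------------------------


def _vec_to_affine(v, center) -> Affine2D:
    tr, tc, theta_deg, log_sr, log_sc, shear = v
    return Affine2D.from_params(
        rotation_deg=theta_deg,
        scale=(np.exp(log_sr), np.exp(log_sc)),
        shear=shear,
        translation=(tr, tc),
        center=center,
        method="optimized",
    )


def linear_register(hist: np.ndarray, mri_slice: np.ndarray, method: str = "nmi"):
    """Optimize a 6-dof affine aligning ``hist`` (moving) to ``mri_slice`` (fixed).

    method: 'nmi' | 'ncc' | 'hog-ecc' | 'identity'.  NCC and HOG-ECC maximize
    the magnitude of the correlation so inverted-contrast modalities align.
    Returns (Affine2D, warped image, report dict); on divergence the identity
    is returned with ``report['success'] = False``.
    """
    from skimage.transform import resize

    method = method.lower()
    fixed = np.asarray(mri_slice, dtype=float)
    moving = np.asarray(hist, dtype=float)
    if moving.shape != fixed.shape:
        moving = resize(moving, fixed.shape, preserve_range=True, anti_aliasing=True)

    def _metrics_pair(f, m):
        return {"nmi": normalized_mutual_information(f, m), "ssim": _ssim(f, m)}

    pre = _metrics_pair(fixed, moving)

    if method == "identity":
        aff = Affine2D.identity()
        report = {"method": method, "pre": pre, "post": pre, "success": True}
        report.update(_overlays(fixed, moving))
        return aff, moving, report

    if method == "hog-ecc":
        fixed_opt, moving_opt = _hog_image(fixed), _hog_image(moving)
        cost_metric = "ncc"
    elif method in ("nmi", "ncc"):
        fixed_opt, moving_opt = fixed, moving
        cost_metric = method
    else:
        raise ValueError(f"unknown linear registration method {method!r}")

    def make_cost(f, m):
        center = ((f.shape[0] - 1) / 2.0, (f.shape[1] - 1) / 2.0)
        tmax = 0.35 * max(f.shape[:2])

        def cost(v):
            # soft bounds keep the coarse search inside the plausible basin
            # (slice matching already gives a rough alignment); without them
            # a degenerate shrink can correlate background with background
            penalty = (
                np.sum(np.clip(np.abs(v[:2]) - tmax, 0, None) ** 2)
                + np.clip(abs(v[2]) - 45.0, 0, None) ** 2
                + 10.0 * np.sum(np.clip(np.abs(v[3:5]) - 0.35, 0, None) ** 2)
                + 10.0 * np.clip(abs(v[5]) - 0.5, 0, None) ** 2
            )
            aff_v = _vec_to_affine(v, center)
            if m.ndim == 3:
                warped = np.stack(
                    [aff_v.warp(m[..., c], output_shape=f.shape[:2], cval=np.nan)
                     for c in range(m.shape[2])],
                    axis=-1,
                )
                valid = np.isfinite(warped).all(axis=-1)
            else:
                warped = aff_v.warp(m, output_shape=f.shape[:2], cval=np.nan)
                valid = np.isfinite(warped)
            if valid.mean() < 0.3:
                return 1.0 + penalty
            fv, wv = f[valid].ravel(), warped[valid].ravel()
            if cost_metric == "ncc":
                return -abs(normalized_cross_correlation(fv, wv)) + penalty
            return -normalized_mutual_information(fv, wv, exclude_background=False) + penalty

        return cost, center

    from skimage.transform import rescale

    chan_ax = -1 if fixed_opt.ndim == 3 else None
    v = np.zeros(6)
    for factor in (4, 2, 1):
        if factor > 1:
            f = rescale(fixed_opt, 1.0 / factor, anti_aliasing=True, channel_axis=chan_ax)
            m = rescale(moving_opt, 1.0 / factor, anti_aliasing=True, channel_axis=chan_ax)
        else:
            f, m = fixed_opt, moving_opt
        if min(f.shape[:2]) < 16:
            continue
        cost, _ = make_cost(f, m)
        v_scaled = v.copy()
        v_scaled[:2] /= factor
        # initial search directions sized to ~1 px / 1 deg / 5% scale steps
        direc = np.diag([1.0, 1.0, 1.0, 0.05, 0.05, 0.05])
        res = minimize(cost, v_scaled, method="Powell",
                       options={"xtol": 1e-4, "ftol": 1e-7, "maxiter": 4000, "direc": direc})
        v = res.x.copy()
        v[:2] *= factor

    center = ((fixed.shape[0] - 1) / 2.0, (fixed.shape[1] - 1) / 2.0)
    aff = _vec_to_affine(v, center)
    warped = aff.warp(moving, output_shape=fixed.shape)
    post = _metrics_pair(fixed, warped)
    success = post["nmi"] >= pre["nmi"] - 1e-9 or post["ssim"] >= pre["ssim"] - 1e-9
    if not success:
        aff, warped, post = Affine2D.identity(), moving, pre
    report = {"method": method, "pre": pre, "post": post, "success": bool(success)}
    report.update(_overlays(fixed, warped))
    return aff, warped, report


def _hog_image(img: np.ndarray, n_orient: int = 3, sigma: float = 2.0) -> np.ndarray:
    """Dense HOG-style feature stack: per-orientation-bin gradient energy,
    Gaussian-pooled, stacked as channels (H, W, n_orient)."""
    rng = img.max() - img.min()
    g = (img - img.min()) / rng if rng > 1e-12 else img
    gy, gx = np.gradient(g)
    mag = np.hypot(gy, gx)
    ang = np.mod(np.arctan2(gy, gx), np.pi)
    chans = []
    for k in range(n_orient):
        lo, hi = k * np.pi / n_orient, (k + 1) * np.pi / n_orient
        chans.append(ndimage.gaussian_filter(mag * ((ang >= lo) & (ang < hi)), sigma))
    return np.stack(chans, axis=-1)


def _overlays(fixed: np.ndarray, warped: np.ndarray) -> dict:
    def norm(x):
        rng = x.max() - x.min()
        return (x - x.min()) / rng if rng > 1e-12 else np.zeros_like(x)

    f, w = norm(fixed), norm(warped)
    overlay = np.stack([w, f, np.zeros_like(f)], axis=-1)  # moving red, fixed green
    return {"overlay": overlay, "difference": np.abs(f - w)}


# ---------------------------------------------------------------------------
# Thin-plate splines
# ---------------------------------------------------------------------------

MAX_LANDMARKS = 500
RECOMMENDED_LANDMARKS = 30


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)  # = r^2 log r
    return np.where(r2 > 0, out, 0.0)


@dataclass
class TPSModel:
    """Thin-plate spline mapping TARGET pixel coords to SOURCE pixel coords.

    Fitted from landmark pairs (source, target): evaluating the model at a
    target point returns the source location whose intensity belongs there,
    i.e. the backward map used for warping.
    """

    centers: np.ndarray          # (n,2) target-side control points
    weights: np.ndarray          # (n,2) radial weights, one column per coord
    affine_coeffs: np.ndarray    # (3,2) rows: const, r, c
    smoothing: float
    bending_energy: float = field(default=0.0)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = pts[:, None, :] - self.centers[None, :, :]
        K = _tps_kernel(np.sum(d * d, axis=2))
        P = np.column_stack([np.ones(len(pts)), pts])
        return K @ self.weights + P @ self.affine_coeffs


def tps_fit(pairs: np.ndarray, smoothing: float = 1e-6) -> TPSModel:
    """Fit a TPS from landmark pairs ``[source_r, source_c, target_r, target_c]``.

    ``smoothing`` is a diagonal regularization of the kernel matrix; at 0 the
    model interpolates the landmarks exactly.  Requires >= 3 non-collinear
    pairs with no duplicate points; the O(n^3) solve is capped at
    ``MAX_LANDMARKS`` pairs.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 4:
        raise ValueError("pairs must be an (n, 4) array of [src_r, src_c, tgt_r, tgt_c]")
    n = len(pairs)
    if n < 3:
        raise ValueError("at least 3 landmark pairs are required")
    if n > MAX_LANDMARKS:
        raise ValueError(f"{n} landmarks exceed the hard cap of {MAX_LANDMARKS} (O(n^3) solve)")
    if n < RECOMMENDED_LANDMARKS:
        warnings.warn(
            f"only {n} landmark pairs; at least {RECOMMENDED_LANDMARKS} (preferably >50) are recommended"
        )
    src, tgt = pairs[:, :2], pairs[:, 2:]
    for name, pts in (("source", src), ("target", tgt)):
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise ValueError(f"duplicate {name} points in landmark list")
    centered = tgt - tgt.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("landmarks are collinear; the TPS system is singular")

    d = tgt[:, None, :] - tgt[None, :, :]
    K = _tps_kernel(np.sum(d * d, axis=2)) + smoothing * np.eye(n)
    P = np.column_stack([np.ones(n), tgt])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K
    A[:n, n:] = P
    A[n:, :n] = P.T
    rhs = np.zeros((n + 3, 2))
    rhs[:n] = src
    sol = np.linalg.solve(A, rhs)
    w, a = sol[:n], sol[n:]
    bend = float(np.trace(w.T @ (K - smoothing * np.eye(n)) @ w))
    return TPSModel(centers=tgt.copy(), weights=w, affine_coeffs=a, smoothing=smoothing,
                    bending_energy=bend)


def tps_apply(model: TPSModel, image: np.ndarray, interpolation: str = "bilinear",
              output_shape=None):
    """Warp ``image`` (source grid) onto the target grid through the TPS.

    Out-of-domain samples (NaN under bilinear interpolation) are filled by
    nearest-neighbor sampling.  Returns (warped, deformation field) where
    the field holds per-target-pixel source coordinates, shape (H, W, 2).
    """
    if interpolation not in ("bilinear", "nearest"):
        raise ValueError("interpolation must be 'bilinear' or 'nearest'")
    image = np.asarray(image, dtype=float)
    if output_shape is None:
        output_shape = image.shape[:2]
    rr, cc = np.meshgrid(np.arange(output_shape[0]), np.arange(output_shape[1]), indexing="ij")
    tgt = np.stack([rr.ravel(), cc.ravel()], axis=1)
    src = model(tgt)
    field = src.reshape(output_shape + (2,))
    order = 1 if interpolation == "bilinear" else 0
    vals = ndimage.map_coordinates(image, [src[:, 0], src[:, 1]], order=order, cval=np.nan)
    bad = ~np.isfinite(vals)
    if bad.any():
        clipped_r = np.clip(src[bad, 0], 0, image.shape[0] - 1)
        clipped_c = np.clip(src[bad, 1], 0, image.shape[1] - 1)
        vals[bad] = ndimage.map_coordinates(image, [clipped_r, clipped_c], order=0)
    return vals.reshape(output_shape), field


def load_landmarks(path: str | Path) -> np.ndarray:
    """Read a landmark CSV ``source_x,source_y,target_x,target_y`` (pixels).

    x is the column and y the row; the returned array is in (r, c) order:
    ``[src_r, src_c, tgt_r, tgt_c]``.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = ["source_x", "source_y", "target_x", "target_y"]
    if not all(c in df.columns for c in cols):
        raise ValueError(f"landmark file must have columns {cols}")
    return df[["source_y", "source_x", "target_y", "target_x"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Stack transformation
# ---------------------------------------------------------------------------


def transform_stack(
    folder: str | Path,
    affine: Affine2D | None,
    tps: TPSModel | None,
    threshold: float | None = None,
    binarize: bool = False,
    output_shape=None,
    out_dir: str | Path | None = None,
) -> dict:
    """Apply affine then TPS to every single-slice NIfTI in ``folder``.

    With ``threshold`` and ``binarize`` set, outputs are thresholded and
    mapped to {0,1} (undoing interpolation de-binarization of masks).
    Files whose grid shape differs from the first file are reported as
    errors and skipped; the rest are still processed.
    """
    folder = Path(folder)
    out_dir = Path(out_dir) if out_dir else folder / "Transformation_results"
    files = sorted(p for p in folder.iterdir() if p.name.endswith((".nii", ".nii.gz")))
    report = {"written": [], "errors": {}}
    if not files:
        warnings.warn(f"no NIfTI files in {folder}; nothing to transform")
        return report
    out_dir.mkdir(parents=True, exist_ok=True)
    ref_shape = None
    for path in files:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        plane = data[:, :, 0] if data.ndim == 3 else data
        if ref_shape is None:
            ref_shape = plane.shape
        elif plane.shape != ref_shape:
            report["errors"][path.name] = f"grid shape {plane.shape} != {ref_shape}"
            continue
        out = plane
        if affine is not None:
            out = affine.warp(out, output_shape=output_shape or out.shape)
        if tps is not None:
            out, _ = tps_apply(tps, out, output_shape=output_shape)
        if threshold is not None and binarize:
            out = (out > threshold).astype(np.float32)
        res = nib.Nifti1Image(out[:, :, None].astype(np.float32), img.affine)
        dest = out_dir / path.name
        nib.save(res, str(dest))
        report["written"].append(dest)
    return report


# ---------------------------------------------------------------------------
# Mask splitting
# ---------------------------------------------------------------------------


@dataclass
class SubregionLabeling:
    labels: np.ndarray
    target_size: int
    sizes: dict[int, int]


def split_mask(mask: np.ndarray, target_size: int = 500, seed: int = 0) -> SubregionLabeling:
    """Partition a binary mask into ~equal connected subregions.

    Seeds come from k-means over distance-transform-weighted mask points
    (k = max(1, round(area/target))); regions grow concentrically and
    synchronously (one frontier ring per round, capped at the target size),
    then leftover pixels are attached to the nearest adjacent subregion so
    every label stays 4-connected and the labels partition the mask exactly.
    """
    from sklearn.cluster import KMeans

    mask = np.asarray(mask).astype(bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty mask")
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    k = max(1, int(round(area / target_size)))
    labels = np.zeros(mask.shape, dtype=np.int32)
    if k == 1:
        labels[mask] = 1
        return SubregionLabeling(labels=labels, target_size=target_size, sizes={1: area})

    rng = np.random.default_rng(seed)
    dt = ndimage.distance_transform_edt(mask)
    coords = np.argwhere(mask)
    # candidate seeds: interior points of the distance transform (boundary
    # pixels make poor growth seeds); k-means over the candidates places k
    # centers with near-equal catchment areas
    interior = coords[dt[coords[:, 0], coords[:, 1]] >= min(1.0, dt.max())]
    cand = interior if len(interior) >= k else coords
    if len(cand) > 20000:
        cand = cand[rng.choice(len(cand), 20000, replace=False)]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(cand.astype(float))

    # snap centers to distinct mask pixels
    seeds = []
    taken = set()
    for ctr in km.cluster_centers_:
        d = np.linalg.norm(coords - ctr, axis=1)
        for idx in np.argsort(d):
            cand = tuple(coords[idx])
            if cand not in taken:
                seeds.append(cand)
                taken.add(cand)
                break
    sizes = {}
    for lab, s in enumerate(seeds, start=1):
        labels[s] = lab
        sizes[lab] = 1

    struct = ndimage.generate_binary_structure(2, 1)  # 4-connectivity

    def grow_round(capped: bool) -> bool:
        grew = False
        # smallest regions claim first so leftovers spread evenly
        for lab in sorted(range(1, k + 1), key=lambda l: (sizes[l], l)):
            if capped and sizes[lab] >= target_size:
                continue
            region = labels == lab
            ring = ndimage.binary_dilation(region, struct) & mask & (labels == 0)
            cand = np.argwhere(ring)
            if len(cand) == 0:
                continue
            if capped:
                room = target_size - sizes[lab]
                if len(cand) > room:
                    d = np.linalg.norm(cand - np.asarray(seeds[lab - 1]), axis=1)
                    cand = cand[np.lexsort((cand[:, 1], cand[:, 0], d))][:room]
            labels[cand[:, 0], cand[:, 1]] = lab
            sizes[lab] += len(cand)
            grew = True
        return grew

    while grow_round(capped=True):
        pass
    while grow_round(capped=False):  # boundary growth for leftovers
        pass

    # disconnected mask components that no seed could reach become new labels
    remaining = mask & (labels == 0)
    if remaining.any():
        comp, ncomp = ndimage.label(remaining, structure=struct)
        for i in range(1, ncomp + 1):
            lab = labels.max() + 1
            labels[comp == i] = lab
            sizes[lab] = int((comp == i).sum())

    sizes = {lab: int((labels == lab).sum()) for lab in np.unique(labels) if lab > 0}
    return SubregionLabeling(labels=labels, target_size=target_size, sizes=sizes)


# ---------------------------------------------------------------------------
# Volume resampling
# ---------------------------------------------------------------------------


def resample_to_reference(source: nib.Nifti1Image, reference: nib.Nifti1Image) -> nib.Nifti1Image:
    """Identity-transform resampling of ``source`` onto the reference grid.

    Output dimensions and voxel spacing equal the reference exactly;
    intensities are linearly interpolated and out-of-field voxels are 0.
    Both volumes are assumed to share their physical origin.
    """
    import SimpleITK as sitk

    def to_sitk(img: nib.Nifti1Image) -> sitk.Image:
        zooms = img.header.get_zooms()[:3]
        if any(z <= 0 for z in zooms):
            raise ValueError("missing or invalid voxel spacing")
        arr = np.asarray(img.dataobj, dtype=np.float32)
        im = sitk.GetImageFromArray(np.transpose(arr, (2, 1, 0)))
        im.SetSpacing(tuple(float(z) for z in zooms))
        return im

    src, ref = to_sitk(source), to_sitk(reference)
    out = sitk.Resample(src, ref, sitk.Transform(), sitk.sitkLinear, 0.0, sitk.sitkFloat32)
    data = np.transpose(sitk.GetArrayFromImage(out), (2, 1, 0))
    result = nib.Nifti1Image(data, reference.affine)
    result.header.set_zooms(reference.header.get_zooms()[:3])
    return result
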