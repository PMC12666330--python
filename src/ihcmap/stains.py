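"""Beer-Lambert optical-density transforms and blind 3-stain color deconvolution.

Brightfield IHC color formation is modelled by the monochromatic Beer-Lambert
law: a pixel with incident (background) intensity ``I0_c`` in channel
``c`` and stain concentrations ``C`` is observed at

    I_c = I0_c * 10 ** (-(C @ M)_c)

where ``M`` is a 3x3 optical-density stain matrix whose rows are the unit
l2-norm OD color vectors of the three chromogens.  ``Y = C M`` is the pixel
OD and ``D = M^-1`` deconvolves OD back into per-stain concentrations,
``C = D Y`` (here with row-vector pixels, ``C = Y M^-1``).

The blind estimation of ``M`` follows a Bayesian K-SVD scheme: pixels are
sparse-coded against the 3-atom dictionary with an adaptive ridge
(variational phase), the atoms are refreshed by rank-1 SVD updates, and a
final empirical K-SVD pass re-codes ambiguous pixels (two leading stain
loadings within a configurable ratio) with hard subset selection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

SENTINEL_RGB = (255, 255, 255)

#: Default stain OD vectors (rows: hematoxylin, DAB, fast blue), unit l2 norm.
#: Hematoxylin/DAB are the standard brightfield literature vectors; the fast
#: blue row is a blue-absorbing chromogen direction well separated from both.
DEFAULT_STAIN_LABELS = ("hematoxylin", "dab", "fastblue")
DEFAULT_STAIN_MATRIX = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.269, 0.568, 0.778],
        [0.920, 0.350, 0.170],
    ]
)


def _unit_rows(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("stain matrix has a zero row")
    return m / norms


def pairwise_angles_deg(m: np.ndarray) -> np.ndarray:
    """Pairwise angular separations (degrees) between the rows of ``m``."""
    u = _unit_rows(m)
    cos = np.clip(u @ u.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    return ang[np.triu_indices(len(u), k=1)]


@dataclass(frozen=True)
class StainModel:
    """3x3 row-normalized stain OD matrix with its deconvolution inverse."""

    M: np.ndarray
    labels: tuple[str, str, str] = DEFAULT_STAIN_LABELS
    provenance: str = "reference"
    D: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        m = _unit_rows(self.M)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        if np.any(m < -1e-12):
            raise ValueError("stain OD vectors must be non-negative")
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > 1e8:
            raise ValueError("stain matrix is singular or nearly collinear")
        object.__setattr__(self, "M", m)
        object.__setattr__(self, "D", np.linalg.inv(m))

    def save(self, path: str | Path) -> None:
        """Write the plain-text reference file (one row per stain: label R G B)."""
        lines = [
            f"{lab} {row[0]:.6f} {row[1]:.6f} {row[2]:.6f}"
            for lab, row in zip(self.labels, self.M)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path, provenance: str = "reference") -> "StainModel":
        labels, rows = [], []
        for line in Path(path).read_text().splitlines():
            parts = line.split()
            if len(parts) != 4:
                continue
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        if len(rows) != 3:
            raise ValueError(f"expected 3 stain rows in {path}, found {len(rows)}")
        return cls(M=np.array(rows), labels=tuple(labels), provenance=provenance)


def rgb_to_od(tile: np.ndarray, i0) -> np.ndarray:
    """Per-channel optical density OD_c = -log10(max(I_c,1)/I0_c).

    Intensities below 1 are clamped to 1 before the log so a fully saturated
    dark pixel maps to the finite OD log10(I0_c).
    """
    i0 = np.asarray(i0, dtype=float)
    if np.any(i0 < 1):
        raise ValueError("I0 components must be >= 1")
    I = np.clip(np.asarray(tile, dtype=float), 1.0, None)
    return -np.log10(I / i0)


def od_to_rgb(od: np.ndarray, i0) -> np.ndarray:
    """Forward Beer-Lambert rendering back to quantized 8-bit RGB."""
    i0 = np.asarray(i0, dtype=float)
    I = i0 * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.round(I), 0, 255).astype(np.uint8)


def sentinel_mask(tile: np.ndarray) -> np.ndarray:
    """Boolean mask of background-sentinel pixels (exactly 255 in all channels)."""
    return np.all(np.asarray(tile) == 255, axis=-1)


def deconvolve(od: np.ndarray, model: StainModel) -> np.ndarray:
    """Concentrations C = Y D for row-vector pixel ODs (no clipping)."""
    od = np.asarray(od, dtype=float)
    return od @ model.D


def convolve(concentrations: np.ndarray, model: StainModel) -> np.ndarray:
    """Forward model Y = C M (pixel OD from concentrations)."""
    return np.asarray(concentrations, dtype=float) @ model.M


# ---------------------------------------------------------------------------
# Blind stain-vector estimation (Bayesian K-SVD hybrid)
# ---------------------------------------------------------------------------


@dataclass
class ConvergenceReport:
    errors: list[float]
    converged: bool
    n_iterations: int
    ambiguous_fraction: float
    message: str = ""


def _sparse_code(X: np.ndarray, M: np.ndarray, ridge: float, max_atoms: int = 2,
                 upgrade_gain: float = 0.5, noise_floor: float = 0.0):
    """Code each OD row of ``X`` against dictionary rows ``M`` using at most
    ``max_atoms`` atoms.

    Each pixel starts from its best single atom; a two-atom subset is
    accepted only when it cuts the residual below ``upgrade_gain`` times the
    single-atom residual AND that residual exceeds ``noise_floor`` —
    otherwise the extra atom would merely chase quantization/measurement
    noise and drag the dictionary update (the pruning role the sparsity
    prior plays in the Bayesian formulation).

    Returns (C, residual_sq) with C (n,3), zero outside the chosen subset.
    Coefficients are (regularized) least squares clipped at 0: stains only
    absorb, so negative loadings are not physical.
    """

    def _code_subsets(subsets):
        n = X.shape[0]
        best_res = np.full(n, np.inf)
        best_C = np.zeros((n, M.shape[0]))
        for idx in subsets:
            A = M[list(idx)]
            G = A @ A.T + ridge * np.eye(len(idx))
            coef = np.linalg.solve(G, A @ X.T).T
            coef = np.clip(coef, 0.0, None)
            res = np.sum((X - coef @ A) ** 2, axis=1)
            better = res < best_res
            if np.any(better):
                best_res[better] = res[better]
                best_C[better] = 0.0
                best_C[np.ix_(better, list(idx))] = coef[better]
        return best_C, best_res

    k = M.shape[0]
    C1, r1 = _code_subsets(list(combinations(range(k), 1)))
    if max_atoms < 2:
        return C1, r1
    C2, r2 = _code_subsets(list(combinations(range(k), 2)))
    upgrade = (r2 < upgrade_gain * r1) & (r1 > noise_floor)
    C = np.where(upgrade[:, None], C2, C1)
    res = np.where(upgrade, r2, r1)
    return C, res


def _ksvd_update(X: np.ndarray, M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """K-SVD dictionary update: rank-1 refresh of each used atom."""
    M = M.copy()
    for k in range(M.shape[0]):
        users = C[:, k] > 1e-10
        if users.sum() < 10:
            continue
        E = X[users] - C[users] @ M + np.outer(C[users, k], M[k])
        # dominant direction of the residual cloud this atom must explain
        _, _, vt = np.linalg.svd(E, full_matrices=False)
        atom = vt[0]
        if atom.sum() < 0:
            atom = -atom
        atom = np.clip(atom, 0.0, None)
        nrm = np.linalg.norm(atom)
        if nrm > 1e-8:
            M[k] = atom / nrm
    return M


def _data_driven_init(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Initial dictionary from the OD cloud's extreme directions.

    Pixel OD vectors are normalized to directions, percentile-trimmed in
    magnitude, and clustered (k-means, k=3); the cluster mean directions
    seed the dictionary.
    """
    from sklearn.cluster import KMeans

    mag = np.linalg.norm(X, axis=1)
    lo, hi = np.percentile(mag, [5, 99.5])
    keep = (mag >= max(lo, 1e-3)) & (mag <= hi)
    dirs = X[keep] / np.linalg.norm(X[keep], axis=1, keepdims=True)
    km = KMeans(n_clusters=3, n_init=5, random_state=int(rng.integers(2**31)))
    km.fit(dirs)
    return _unit_rows(np.clip(km.cluster_centers_, 1e-6, None))


def _nmf_init(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from sklearn.decomposition import NMF

    nmf = NMF(
        n_components=3,
        init="nndsvda",
        max_iter=400,
        random_state=int(rng.integers(2**31)),
    )
    nmf.fit(np.clip(X, 0, None))
    return _unit_rows(np.clip(nmf.components_, 1e-6, None))


def _match_rows_to_reference(M: np.ndarray, ref: np.ndarray):
    """Permute rows of M to the reference rows by maximal cosine similarity."""
    from scipy.optimize import linear_sum_assignment

    cos = _unit_rows(M) @ _unit_rows(ref).T
    ri, ci = linear_sum_assignment(-cos)
    perm = np.empty(3, dtype=int)
    perm[ci] = ri
    return M[perm], perm


def estimate_stain_vectors(
    grid,
    init="data",
    od_threshold: float = 0.05,
    i0=(255, 255, 255),
    max_iter: int = 50,
    tol: float = 1e-5,
    seed: int = 0,
    max_pixels: int = 30000,
    ambiguity_ratio: float = 0.8,
    reference: StainModel | None = None,
):
    """Blind 3-stain estimation from a background-removed tile grid.

    Parameters
    ----------
    grid : TileGrid
        Background-removed grid; sentinel pixels and pixels with scalar OD
        below ``od_threshold`` are excluded from the fit.
    init : StainModel | "data" | "nmf"
        Dictionary initialization.  ``"data"`` (default) seeds from the OD
        cloud's extreme directions; ``"nmf"`` from a non-negative matrix
        factorization; a StainModel uses its rows directly.
    reference : StainModel, optional
        Rows of the result are label-matched against this model (defaults to
        the init model when that is a StainModel, else the built-in
        reference vectors).

    Returns
    -------
    (StainModel, ConvergenceReport)
    """
    rng = np.random.default_rng(seed)
    X = _collect_od_pixels(grid, i0, od_threshold, max_pixels, rng)
    if X.shape[0] < 30:
        raise ValueError("too few foreground OD pixels to estimate stains")

    # three effective stains need three directions of variance; quantization
    # noise alone puts the third singular value near 0.005 of the first,
    # genuine 3-stain clouds at 0.1 or higher
    svals = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    rank_ok = svals[2] / max(svals[0], 1e-12) > 0.02

    if isinstance(init, StainModel):
        M = init.M.copy()
        labels = init.labels
        ref = reference.M if reference is not None else init.M
        ref_labels = reference.labels if reference is not None else init.labels
    else:
        if init == "nmf":
            M = _nmf_init(X, rng)
        elif init == "data":
            M = _data_driven_init(X, rng)
        else:
            raise ValueError(f"unknown init method {init!r}")
        refmod = reference if reference is not None else StainModel(DEFAULT_STAIN_MATRIX)
        ref, ref_labels = refmod.M, refmod.labels
        labels = ref_labels

    errors = []
    converged = False
    prev_M = M.copy()
    ridge = 1e-4
    floor = 0.0
    for it in range(max_iter):
        C, res = _sparse_code(X, M, ridge=ridge, noise_floor=floor)
        err = float(np.sqrt(res.mean()))
        if errors and err > errors[-1] + 1e-9:
            # a dictionary update made coding worse: revert and stop
            M = prev_M
            converged = True
            break
        errors.append(err)
        if len(errors) > 1 and abs(errors[-2] - errors[-1]) <= tol * max(errors[-2], 1e-12):
            converged = True
            break
        prev_M = M.copy()
        M = _ksvd_update(X, M, C)
        # noise-precision update (variational flavor): the sparsity floor
        # tracks the current residual level so pure pixels stay one-atom
        floor = 3.0 * float(np.median(res))

    # pure-pixel snap: re-anchor each atom on the pixels its stain explains
    # essentially alone.  Mixed pixels let the sparse coder absorb part of an
    # atom's error into a co-occurring atom's coefficient, which can stall the
    # alternation at the initialization; near-pure pixels are immune to that.
    # Each snap is accepted only if it lowers the hard coding error.
    _, res_now = _sparse_code(X, M, ridge=0.0, noise_floor=floor)
    err_now = float(res_now.mean())
    norm2 = np.clip(np.sum(X * X, axis=1), 1e-12, None)
    for pure_tol in (0.05, 0.02, 0.01):
        C1, r1 = _sparse_code(X, M, ridge=0.0, max_atoms=1)
        rel = r1 / norm2
        M_snap = M.copy()
        for k in range(3):
            sel = (rel < pure_tol) & (C1[:, k] > 1e-10)
            if sel.sum() < 100:
                continue
            _, _, vt = np.linalg.svd(X[sel], full_matrices=False)
            atom = vt[0] if vt[0].sum() >= 0 else -vt[0]
            atom = np.clip(atom, 0.0, None)
            if np.linalg.norm(atom) > 1e-8:
                M_snap[k] = atom / np.linalg.norm(atom)
        _, res_snap = _sparse_code(X, M_snap, ridge=0.0, noise_floor=floor)
        if float(res_snap.mean()) < err_now - 1e-12:
            M = M_snap
            err_now = float(res_snap.mean())

    # empirical refinement of ambiguous pixels: hard (unregularized) re-coding
    C, _ = _sparse_code(X, M, ridge=0.0, noise_floor=floor)
    order = np.sort(np.abs(C), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(order[:, 2] > 1e-10, order[:, 1] / order[:, 2], 0.0)
    ambiguous = ratio > ambiguity_ratio
    amb_frac = float(ambiguous.mean())
    if ambiguous.sum() >= 30:
        Ca, _ = _sparse_code(X[ambiguous], M, ridge=0.0, max_atoms=1)

        C2 = C.copy()
        C2[ambiguous] = Ca
        M_refined = _ksvd_update(X, M, C2)
        _, res_refined = _sparse_code(X, M_refined, ridge=0.0, noise_floor=floor)
        if errors and float(np.sqrt(res_refined.mean())) <= errors[-1] + 1e-9:
            M = M_refined

    msg = ""
    if not rank_ok:
        converged = False
        msg = "OD cloud is rank-deficient (<3 effective stains); best-effort matrix"
        warnings.warn(msg)

    M_matched, _ = _match_rows_to_reference(M, ref)
    model = StainModel(M=M_matched, labels=tuple(ref_labels), provenance="estimated")
    report = ConvergenceReport(
        errors=errors,
        converged=converged,
        n_iterations=len(errors),
        ambiguous_fraction=amb_frac,
    )
    report.message = msg
    return model, report


def _collect_od_pixels(grid, i0, od_threshold, max_pixels, rng):
    """Pool foreground OD vectors from all tiles of a grid (or a bare array)."""
    tiles = grid.tiles.values() if hasattr(grid, "tiles") else [grid]
    chunks = []
    for tile in tiles:
        od = rgb_to_od(tile, i0)
        keep = ~sentinel_mask(tile) & (od.mean(axis=-1) >= od_threshold)
        if keep.any():
            chunks.append(od[keep])
    if not chunks:
        return np.empty((0, 3))
    X = np.concatenate(chunks, axis=0)
    if X.shape[0] > max_pixels:
        X = X[rng.choice(X.shape[0], max_pixels, replace=False)]
    return X


# ---------------------------------------------------------------------------
# Percentiles and cross-slide normalization
# ---------------------------------------------------------------------------


@dataclass
class StainPercentiles:
    values: dict[str, float]
    p: float = 99.9
    sample_fraction: float = 0.10

    def __post_init__(self):
        if not (0 < self.p < 100):
            raise ValueError("percentile must be in (0,100)")
        self.values = {k: max(0.0, float(v)) for k, v in self.values.items()}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"percentile": self.p, "sample_fraction": self.sample_fraction, "values": self.values},
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "StainPercentiles":
        d = json.loads(Path(path).read_text())
        return cls(values=d["values"], p=d["percentile"], sample_fraction=d.get("sample_fraction", 0.10))


def compute_percentiles(
    grid,
    model: StainModel,
    p: float = 99.9,
    sample_fraction: float = 0.10,
    seed: int = 0,
    i0=(255, 255, 255),
) -> StainPercentiles:
    """Per-stain concentration percentile over pooled 10% pixel samples."""
    rng = np.random.default_rng(seed)
    tiles = grid.tiles.values() if hasattr(grid, "tiles") else [grid]
    samples = []
    for tile in tiles:
        od = rgb_to_od(tile, i0)
        keep = ~sentinel_mask(tile)
        if not keep.any():
            continue
        conc = deconvolve(od[keep], model)
        n = conc.shape[0]
        take = max(1, int(round(sample_fraction * n)))
        samples.append(conc[rng.choice(n, take, replace=False)])
    if not samples:
        raise ValueError("no non-sentinel pixels to sample for percentiles")
    pooled = np.concatenate(samples, axis=0)
    vals = np.percentile(pooled, p, axis=0)
    return StainPercentiles(
        values={lab: float(v) for lab, v in zip(model.labels, vals)},
        p=p,
        sample_fraction=sample_fraction,
    )


def normalize_concentrations(
    grid,
    model: StainModel,
    own: StainPercentiles,
    reference: StainPercentiles,
    i0=(255, 255, 255),
):
    """Rescale each stain channel by reference_p/own_p and re-render to RGB.

    Sentinel pixels pass through unchanged; the output grid is tagged
    ``stainnormalized``.
    """
    if abs(own.p - reference.p) > 1e-9:
        raise ValueError("own and reference percentiles use different p")
    scale = np.empty(3)
    for i, lab in enumerate(model.labels):
        ov = own.values.get(lab, 0.0)
        if ov <= 0:
            raise ValueError(f"own percentile is zero for stain {lab!r}")
        scale[i] = reference.values.get(lab, ov) / ov

    def _norm(tile):
        od = rgb_to_od(tile, i0)
        sh = tile.shape[:2]
        conc = deconvolve(od.reshape(-1, 3), model) * scale
        rgb = od_to_rgb(convolve(conc, model).reshape(sh + (3,)), i0)
        sm = sentinel_mask(tile)
        rgb[sm] = 255
        # re-rendered tissue must not collide with the sentinel
        tissue_sat = ~sm & sentinel_mask(rgb)
        rgb[tissue_sat] = 254
        return rgb

    return grid.map_tiles(_norm, stage="stainnormalized")
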