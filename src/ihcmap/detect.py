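"""Rule-based detection of cells, microglia, and myelin-positive pixels.

All detectors operate on per-pixel stain-concentration channels (clipped to
[0, 3]).  Cells and microglia follow a multi-pass component pipeline:

1. MAD threshold on the stain channel (foreground = value > median + k*MAD);
2. first pass: size floor, then per-component removal of the lowest-intensity
   pixel fraction;
3. second pass: mean-intensity/size ceilings (cells) or a size-OR-intensity
   keep rule plus a size ceiling (microglia);
4. third pass: per-component trim of the pixels most distant from the
   intensity-weighted centroid, then a size floor;
5. distance-transform watershed to split touching objects, then a size floor
   on the fragments.

Myelin positives come from Wolf's adaptive threshold on the non-negative
pixels of the myelin channel.  Components use 8-connectivity throughout.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

CLIP_LO, CLIP_HI = 0.0, 3.0
_STRUCT8 = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------------------
# Parameter bundles
# ---------------------------------------------------------------------------


@dataclass
class CellParams:
    mad_k: float = 3.0
    min_size_1: int = 30
    low_intensity_pct_1: float = 10.0
    max_mean_intensity_2: float = 3.0
    max_size_2: int = 10000
    centroid_trim_pct_3: float = 10.0
    min_size_3: int = 20
    min_size_post_watershed: int = 15

    def __post_init__(self):
        for p in (self.low_intensity_pct_1, self.centroid_trim_pct_3):
            if not 0 <= p <= 100:
                raise ValueError("percentages must be in [0, 100]")
        for s in (self.min_size_1, self.max_size_2, self.min_size_3, self.min_size_post_watershed):
            if s < 0:
                raise ValueError("sizes must be >= 0")

    FILENAME = "cell_detection_parameters.json"


@dataclass
class MicrogliaParams:
    mad_k: float = 3.0
    min_size_1: int = 20
    low_intensity_pct_1: float = 10.0
    size_req_min: int = 300          # "should be set at a high value"
    intensity_req_min: float = 0.5
    intensity_req_count: int = 20
    max_size_2: int = 10000
    centroid_trim_pct_3: float = 10.0
    min_size_3: int = 15

    def __post_init__(self):
        for p in (self.low_intensity_pct_1, self.centroid_trim_pct_3):
            if not 0 <= p <= 100:
                raise ValueError("percentages must be in [0, 100]")

    FILENAME = "microglia_detection_parameters.json"


@dataclass
class MyelinParams:
    alpha: float = 1.0     # local variance weight
    k: float = 0.3         # threshold sensitivity
    window_px: int = 15
    clip_lo: float = CLIP_LO
    clip_hi: float = CLIP_HI

    def __post_init__(self):
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ValueError("window_px must be odd and >= 3")

    FILENAME = "myelin_detection_parameters.json"


def save_params(params, directory: str | Path) -> Path:
    path = Path(directory) / params.FILENAME
    path.write_text(json.dumps(asdict(params), indent=2))
    return path


def load_params(cls, directory: str | Path):
    path = Path(directory) / cls.FILENAME
    return cls(**json.loads(path.read_text()))


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------


def clip_channel(channel: np.ndarray, lo: float = CLIP_LO, hi: float = CLIP_HI) -> np.ndarray:
    """Truncate concentrations below ``lo`` and above ``hi`` (defaults [0, 3])."""
    return np.clip(np.asarray(channel, dtype=float), lo, hi)


def mad_mask(channel: np.ndarray, k: float, exclude: np.ndarray | None = None) -> np.ndarray:
    """Foreground mask: channel > median + k * MAD over non-excluded pixels.

    MAD is the median absolute deviation median(|x - median(x)|).  A zero MAD
    (e.g. constant channel) falls back to ``channel > median`` with a warning.
    """
    channel = np.asarray(channel, dtype=float)
    vals = channel[~exclude] if exclude is not None else channel.ravel()
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    if mad == 0:
        warnings.warn("MAD is zero; falling back to median threshold")
        mask = channel > med
    else:
        mask = channel > med + k * mad
    if exclude is not None:
        mask &= ~exclude
    return mask


@dataclass
class ComponentSet:
    labels: np.ndarray
    areas: np.ndarray
    mean_intensities: np.ndarray
    centroids: np.ndarray  # intensity-weighted, (n, 2) in (r, c)
    intermediates: dict = field(default_factory=dict, repr=False)

    @property
    def count(self) -> int:
        return len(self.areas)


def _relabel(mask: np.ndarray):
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    return labels, n


def _summarize(mask: np.ndarray, intensity: np.ndarray, intermediates=None) -> ComponentSet:
    labels, n = _relabel(mask)
    if n == 0:
        return ComponentSet(labels=labels, areas=np.zeros(0, int),
                            mean_intensities=np.zeros(0), centroids=np.zeros((0, 2)),
                            intermediates=intermediates or {})
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(intensity), labels, idx).astype(int)
    means = ndimage.mean(intensity, labels, idx)
    w = np.clip(intensity, 1e-9, None)
    centroids = np.array(ndimage.center_of_mass(w, labels, idx))
    return ComponentSet(labels=labels, areas=areas, mean_intensities=np.asarray(means),
                        centroids=centroids, intermediates=intermediates or {})


def _drop_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    if min_size <= 0:
        return mask
    labels, n = _relabel(mask)
    if n == 0:
        return mask
    areas = ndimage.sum_labels(np.ones(mask.shape), labels, np.arange(1, n + 1))
    keep = np.concatenate([[False], areas >= min_size])
    return keep[labels]


def _remove_low_intensity(mask: np.ndarray, intensity: np.ndarray, pct: float) -> np.ndarray:
    """Within each component, drop pixels strictly below the ``pct``-th
    within-component intensity percentile (ties are kept)."""
    if pct <= 0:
        return mask
    labels, n = _relabel(mask)
    out = mask.copy()
    for lab in range(1, n + 1):
        comp = labels == lab
        vals = intensity[comp]
        thr = np.percentile(vals, pct)
        out[comp & (intensity < thr)] = False
    return out


def _centroid_trim(mask: np.ndarray, intensity: np.ndarray, pct: float) -> np.ndarray:
    """Per component, remove the ``pct``% of pixels most distant from the
    intensity-weighted centroid (Euclidean pixel distance); re-labels after."""
    if pct <= 0:
        return mask
    labels, n = _relabel(mask)
    out = mask.copy()
    for lab in range(1, n + 1):
        comp = labels == lab
        pix = np.argwhere(comp)
        w = np.clip(intensity[comp], 1e-9, None)
        ctr = (pix * w[:, None]).sum(axis=0) / w.sum()
        d = np.linalg.norm(pix - ctr, axis=1)
        cut = np.percentile(d, 100.0 - pct)
        drop = pix[d > cut]
        out[drop[:, 0], drop[:, 1]] = False
    return out


def _watershed_split(mask: np.ndarray, min_seed_distance: int = 3) -> np.ndarray:
    """Distance-transform watershed; seeds are local maxima of the EDT with a
    minimum separation, so touching convex objects split along the waist."""
    from skimage.feature import peak_local_max
    from skimage.segmentation import watershed

    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=min_seed_distance, labels=mask,
                           exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        labels, _ = _relabel(mask)
        return labels
    return watershed(-dist, markers=markers, mask=mask)


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

CHANNELS = {"hematoxylin": 0, "microglia": 1, "myelin": 2}


def _get_channel(tile_concentrations: np.ndarray, name: str) -> np.ndarray:
    tc = np.asarray(tile_concentrations, dtype=float)
    if tc.ndim != 3 or tc.shape[2] <= CHANNELS[name]:
        raise ValueError(f"missing {name} channel in concentration tile")
    return tc[..., CHANNELS[name]]


def detect_cells(tile_concentrations: np.ndarray, params: CellParams,
                 exclude: np.ndarray | None = None,
                 keep_intermediates: bool = False) -> ComponentSet:
    """Multi-pass nucleus detection on the hematoxylin channel."""
    chan = clip_channel(_get_channel(tile_concentrations, "hematoxylin"))
    inter: dict = {}
    mask = mad_mask(chan, params.mad_k, exclude=exclude)
    if keep_intermediates:
        inter["pass0_mad"] = mask.copy()
    # pass 1: size floor, then strip the dimmest pixel fraction per component
    mask = _drop_small(mask, params.min_size_1)
    mask = _remove_low_intensity(mask, chan, params.low_intensity_pct_1)
    if keep_intermediates:
        inter["pass1"] = mask.copy()
    # pass 2: mean-intensity and size ceilings
    labels, n = _relabel(mask)
    if n:
        idx = np.arange(1, n + 1)
        means = np.asarray(ndimage.mean(chan, labels, idx))
        areas = np.asarray(ndimage.sum_labels(np.ones(mask.shape), labels, idx))
        keep = np.concatenate([[False], (means <= params.max_mean_intensity_2)
                               & (areas <= params.max_size_2)])
        mask = keep[labels]
    if keep_intermediates:
        inter["pass2"] = mask.copy()
    # pass 3: centroid trim, then size floor
    mask = _centroid_trim(mask, chan, params.centroid_trim_pct_3)
    mask = _drop_small(mask, params.min_size_3)
    if keep_intermediates:
        inter["pass3"] = mask.copy()
    # watershed + fragment floor
    ws = _watershed_split(mask)
    frag_ok = np.zeros(mask.shape, dtype=bool)
    for lab in range(1, ws.max() + 1):
        frag = ws == lab
        if frag.sum() >= params.min_size_post_watershed:
            frag_ok |= frag
    final = np.where(frag_ok, ws, 0)
    if keep_intermediates:
        inter["watershed"] = final.copy()
    return _summarize_watershed(final, chan, inter)


def _summarize_watershed(ws_labels: np.ndarray, intensity: np.ndarray, inter) -> ComponentSet:
    present = np.unique(ws_labels)
    present = present[present > 0]
    if len(present) == 0:
        return ComponentSet(labels=np.zeros_like(ws_labels), areas=np.zeros(0, int),
                            mean_intensities=np.zeros(0), centroids=np.zeros((0, 2)),
                            intermediates=inter)
    remap = np.zeros(ws_labels.max() + 1, dtype=np.int32)
    remap[present] = np.arange(1, len(present) + 1)
    labels = remap[ws_labels]
    idx = np.arange(1, len(present) + 1)
    areas = ndimage.sum_labels(np.ones(labels.shape), labels, idx).astype(int)
    means = np.asarray(ndimage.mean(intensity, labels, idx))
    w = np.clip(intensity, 1e-9, None)
    centroids = np.array(ndimage.center_of_mass(w, labels, idx))
    return ComponentSet(labels=labels, areas=areas, mean_intensities=means,
                        centroids=centroids, intermediates=inter)


def detect_microglia(tile_concentrations: np.ndarray, params: MicrogliaParams,
                     exclude: np.ndarray | None = None,
                     keep_intermediates: bool = False) -> ComponentSet:
    """Microglia detection on the DAB channel.

    Pass 2 keeps a component iff it satisfies the size requirement
    (area >= size_req_min) OR the intensity requirement (at least
    intensity_req_count pixels at or above intensity_req_min); survivors are
    then subject to the upper size ceiling.
    """
    chan = clip_channel(_get_channel(tile_concentrations, "microglia"))
    inter: dict = {}
    mask = mad_mask(chan, params.mad_k, exclude=exclude)
    if keep_intermediates:
        inter["pass0_mad"] = mask.copy()
    mask = _drop_small(mask, params.min_size_1)
    mask = _remove_low_intensity(mask, chan, params.low_intensity_pct_1)
    if keep_intermediates:
        inter["pass1"] = mask.copy()
    labels, n = _relabel(mask)
    if n:
        idx = np.arange(1, n + 1)
        areas = np.asarray(ndimage.sum_labels(np.ones(mask.shape), labels, idx))
        hot = np.asarray(
            ndimage.sum_labels((chan >= params.intensity_req_min).astype(float), labels, idx)
        )
        size_ok = areas >= params.size_req_min
        intensity_ok = hot >= params.intensity_req_count
        keep = np.concatenate([[False], (size_ok | intensity_ok) & (areas <= params.max_size_2)])
        mask = keep[labels]
    if keep_intermediates:
        inter["pass2"] = mask.copy()
    mask = _centroid_trim(mask, chan, params.centroid_trim_pct_3)
    mask = _drop_small(mask, params.min_size_3)
    if keep_intermediates:
        inter["pass3"] = mask.copy()
    ws = _watershed_split(mask)
    if keep_intermediates:
        inter["watershed"] = ws.copy()
    return _summarize_watershed(ws, chan, inter)


def wolf_threshold_map(channel: np.ndarray, params: MyelinParams) -> np.ndarray:
    """Per-pixel Wolf adaptive threshold map.

    T = m - k * (1 - alpha * s / R) * (m - M_min) with local mean ``m`` and
    local standard deviation ``s`` in a ``window_px`` square (reflective
    padding), the global channel minimum ``M_min`` and the global maximum of
    the local standard deviation ``R``.  alpha = 1 recovers the classic
    Wolf-Jolion rule.
    """
    if params.window_px % 2 == 0:
        raise ValueError("window_px must be odd")
    chan = np.asarray(channel, dtype=float)
    w = params.window_px
    m = ndimage.uniform_filter(chan, size=w, mode="reflect")
    m2 = ndimage.uniform_filter(chan * chan, size=w, mode="reflect")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    R = s.max()
    mmin = chan.min()
    ratio = s / R if R > 0 else np.zeros_like(s)
    return m - params.k * (1.0 - params.alpha * ratio) * (m - mmin)


def detect_myelin(tile_concentrations: np.ndarray, params: MyelinParams,
                  exclude: np.ndarray | None = None):
    """Myelin positives: non-negative pixels strictly above the Wolf threshold.

    ``exclude`` marks sentinel-background pixels, which are never positive.
    Returns (binary mask, positive pixel count).
    """
    raw = _get_channel(tile_concentrations, "myelin")
    chan = clip_channel(raw, params.clip_lo, params.clip_hi)
    thr = wolf_threshold_map(chan, params)
    # epsilon guards against float cancellation making the threshold -1e-16
    # in perfectly flat regions, where "strictly above" must stay false
    mask = (raw >= 0) & (chan > thr + 1e-9)
    if exclude is not None:
        mask &= ~exclude
    return mask, int(mask.sum())
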