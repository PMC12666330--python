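"""Shared fixtures: seeded phantoms reused across test modules."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from ihcmap import phantoms, preprocess, register, stains
from ihcmap.tiles import TileGrid


def row_angles_deg(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Angles between optimally matched rows of two stain matrices."""
    U = A / np.linalg.norm(A, axis=1, keepdims=True)
    V = B / np.linalg.norm(B, axis=1, keepdims=True)
    cos = np.clip(U @ V.T, -1, 1)
    ri, ci = linear_sum_assignment(-cos)
    return np.degrees(np.arccos(cos[ri, ci]))


def perturb_rows(M: np.ndarray, deg: float, seed: int) -> np.ndarray:
    """Rotate each unit row of M by ``deg`` degrees in a random direction."""
    rng = np.random.default_rng(seed)
    U = M / np.linalg.norm(M, axis=1, keepdims=True)
    out = []
    for row in U:
        v = rng.standard_normal(3)
        v -= (v @ row) * row
        v /= np.linalg.norm(v)
        th = np.deg2rad(deg)
        out.append(np.cos(th) * row + np.sin(th) * v)
    return np.abs(np.array(out))


def truth_background_removed(phantom) -> TileGrid:
    """Sentinelize a phantom grid using the generator's own truth mask."""
    tiles = {}
    for k, t in phantom.tiles.tiles.items():
        out = t.copy()
        out[~phantom.tissue_mask(k)] = 255
        tiles[k] = out
    return TileGrid(tiles=tiles, stage="bgremoved")


@pytest.fixture(scope="session")
def ihc_phantom():
    """Standard noise-free slide phantom (3x3 grid)."""
    return phantoms.gen_ihc_phantom(seed=1, grid=(3, 3), tile_px=256)


@pytest.fixture(scope="session")
def background_model(ihc_phantom):
    return preprocess.estimate_background(ihc_phantom.tiles)


@pytest.fixture(scope="session")
def bg_removed(ihc_phantom, background_model):
    return preprocess.remove_background(ihc_phantom.tiles, background_model)


@pytest.fixture(scope="session")
def noisy_stain_phantom():
    """Phantom with perturbed truth stain vectors and OD noise sigma=0.02."""
    truth_M = perturb_rows(stains.DEFAULT_STAIN_MATRIX, 8.0, 11)
    ph = phantoms.gen_ihc_phantom(
        seed=5, grid=(3, 3), tile_px=256, stain_matrix=truth_M,
        od_noise_sigma=0.02, microglia_per_tile=14,
    )
    return ph


@pytest.fixture(scope="session")
def vignette_phantom():
    """Normal-appearing white-matter slide with a 30% radial vignette."""
    return phantoms.gen_ihc_phantom(
        seed=3, grid=(5, 5), tile_px=256, vignette_strength=0.3, lesion_severity=0.0
    )


@pytest.fixture(scope="session")
def histology_template():
    return phantoms.make_histology_template(seed=0, size=96)


@pytest.fixture(scope="session")
def mri_phantom(histology_template):
    aff = register.Affine2D.from_params(
        rotation_deg=5, scale=(1.05, 1.05), translation=(3, -2), center=(47.5, 47.5)
    )
    return phantoms.gen_mri_phantom(
        histology_template, n_slices=16, truth_slice=7, affine_params=aff,
        warp_amplitude=2.0, seed=2, orientation=3, noise_sigma=0.02,
    )
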