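"""Tiled whole-slide data model, acquisition metadata and overview rendering.

A scanned slide arrives as a rectangular grid of medium-size RGB tiles named
``tile_r{row}_c{col}.tif`` (0-based, row-major, origin top-left) plus a
metadata dump stating the tile size, grid layout and pixel size.  This module
parses that metadata, loads/saves tile grids through their processing stages,
splits medium tiles into the small analysis tiles, and stitches downsampled
overviews (including the black-background registration template).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

STAGES = ("raw", "Lnorm", "bgremoved", "illumcorrected", "stainnormalized", "small")

#: Stage-suffixed folder names mirroring the pipeline's directory layout.
STAGE_DIRS = {
    "raw": "Tiles-Medium",
    "Lnorm": "Tiles-Medium-L-Channel-Normalized",
    "bgremoved": "Tiles-Medium-L-Channel-Normalized-BG-Removed",
    "illumcorrected": "Tiles-Medium-L-Channel-Normalized-BG-removed-Illumination-Corrected",
    "stainnormalized": "Tiles-Medium-L-Channel-Normalized-BG-removed-Illumination-Corrected-Stain-Normalized",
    "small": "Tiles-Small",
}


@dataclass(frozen=True)
class AcquisitionMetadata:
    tile_width_px: int
    tile_height_px: int
    grid_rows: int
    grid_cols: int
    pixel_size_um: float
    stain_names: tuple[str, ...] = ("hematoxylin", "dab", "fastblue")

    def __post_init__(self):
        for name in ("tile_width_px", "tile_height_px", "grid_rows", "grid_cols"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    def to_csv(self, path: str | Path) -> None:
        header = "key,value"
        rows = [
            f"tile_width_px,{self.tile_width_px}",
            f"tile_height_px,{self.tile_height_px}",
            f"grid_rows,{self.grid_rows}",
            f"grid_cols,{self.grid_cols}",
            f"pixel_size_um,{self.pixel_size_um}",
            f"stain_names,{';'.join(self.stain_names)}",
        ]
        Path(path).write_text("\n".join([header] + rows) + "\n")


_KEY_ALIASES = {
    "tilewidth": "tile_width_px",
    "tilewidthpx": "tile_width_px",
    "tileheight": "tile_height_px",
    "tileheightpx": "tile_height_px",
    "gridrows": "grid_rows",
    "rows": "grid_rows",
    "gridcols": "grid_cols",
    "cols": "grid_cols",
    "columns": "grid_cols",
    "pixelsize": "pixel_size_um",
    "pixelsizeum": "pixel_size_um",
    "pixelwidth": "pixel_size_um",
    "stains": "stain_names",
    "stainnames": "stain_names",
}

_REQUIRED = ("tile_width_px", "tile_height_px", "grid_rows", "grid_cols", "pixel_size_um")


def parse_metadata(text: str) -> AcquisitionMetadata:
    """Parse a metadata dump into validated :class:`AcquisitionMetadata`.

    Accepts both flat ``key=value`` / ``key: value`` lines and the two-column
    ``key,value`` CSV the pipeline writes.  A ``tile size`` given as
    ``WxH`` fills both width and height.  Unknown keys are ignored; a missing
    required key or a duplicate key with a conflicting value is an error.
    """
    found: dict[str, object] = {}

    def _store(key: str, value):
        if key in found and found[key] != value:
            raise ValueError(f"conflicting duplicate values for metadata key {key!r}")
        found[key] = value

    for raw_line in text.splitlines():
        line = raw_line.strip()
        if not line or line.startswith("#"):
            continue
        m = re.match(r"^([^=:,]+)[=:,](.+)$", line)
        if not m:
            continue
        rawkey, rawval = m.group(1).strip(), m.group(2).strip()
        norm = re.sub(r"[^a-z0-9]", "", rawkey.lower())
        key = _KEY_ALIASES.get(norm, norm)
        if key == "tilesize":
            wh = re.match(r"^(\d+)\s*[x×]\s*(\d+)$", rawval)
            if wh:
                _store("tile_width_px", int(wh.group(1)))
                _store("tile_height_px", int(wh.group(2)))
            continue
        if key in ("tile_width_px", "tile_height_px", "grid_rows", "grid_cols"):
            _store(key, int(float(rawval)))
        elif key == "pixel_size_um":
            _store(key, float(re.sub(r"[^\d.eE+-]", "", rawval)))
        elif key == "stain_names":
            _store(key, tuple(s.strip() for s in re.split(r"[;|]", rawval) if s.strip()))

    if "tile_width_px" not in found or "tile_height_px" not in found:
        raise ValueError("missing tile size (tile_width_px / tile_height_px)")
    for key in _REQUIRED:
        if key not in found:
            raise ValueError(f"missing required metadata key: {key}")
    return AcquisitionMetadata(**found)  # type: ignore[arg-type]


DEFAULT_TILE_EXPORT_TEMPLATE = """\
// Tile export script (QuPath) — generated, do not edit
def tileWidth = {tile_width}
def tileHeight = {tile_height}
def server = getCurrentServer()
new TileExporter(getCurrentImageData())
    .tileSize(tileWidth, tileHeight)
    .imageExtension('.tif')
    .writeTiles('Data/Tiles-Medium')
"""


def emit_tile_export_script(
    meta: AcquisitionMetadata, template: str = DEFAULT_TILE_EXPORT_TEMPLATE
) -> str:
    """Fill the tile-export script template with the acquisition tile size."""
    if meta.tile_width_px <= 0 or meta.tile_height_px <= 0:
        raise ValueError("tile size must be positive")
    return template.format(tile_width=meta.tile_width_px, tile_height=meta.tile_height_px)


def tile_name(row: int, col: int, truncated: bool = False) -> str:
    suffix = "_edge" if truncated else ""
    return f"tile_r{row}_c{col}{suffix}.tif"


@dataclass
class TileGrid:
    """Rectangular grid of uniform 8-bit RGB tiles addressed by (row, col)."""

    tiles: dict[tuple[int, int], np.ndarray]
    stage: str = "raw"
    truncated: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.tiles:
            raise ValueError("empty tile grid")
        rows = {r for r, _ in self.tiles}
        cols = {c for _, c in self.tiles}
        expected = {(r, c) for r in range(max(rows) + 1) for c in range(max(cols) + 1)}
        missing = expected - set(self.tiles)
        if missing:
            raise ValueError(f"tile grid is not a full rectangle; missing {sorted(missing)[:5]}")
        shapes = {self.tiles[k].shape for k in self.tiles if k not in self.truncated}
        if len(shapes) > 1:
            raise ValueError(f"non-uniform tile shapes: {shapes}")
        for k, t in self.tiles.items():
            if t.ndim != 3 or t.shape[2] != 3 or t.dtype != np.uint8:
                raise ValueError(f"tile {k} is not 8-bit RGB")

    @property
    def n_rows(self) -> int:
        return max(r for r, _ in self.tiles) + 1

    @property
    def n_cols(self) -> int:
        return max(c for _, c in self.tiles) + 1

    @property
    def tile_shape(self):
        key = next(k for k in sorted(self.tiles) if k not in self.truncated)
        return self.tiles[key].shape

    def map_tiles(self, fn, stage: str | None = None) -> "TileGrid":
        """Apply ``fn(tile) -> tile`` to every tile; returns a new grid."""
        new = {k: np.ascontiguousarray(fn(v)) for k, v in self.tiles.items()}
        return TileGrid(tiles=new, stage=stage or self.stage, truncated=self.truncated)

    def stitch(self) -> np.ndarray:
        """Assemble the full-resolution montage (row-major, origin top-left)."""
        th, tw, _ = self.tile_shape
        heights = [self.tiles[(r, 0)].shape[0] for r in range(self.n_rows)]
        widths = [self.tiles[(0, c)].shape[1] for c in range(self.n_cols)]
        out = np.zeros((sum(heights), sum(widths), 3), dtype=np.uint8)
        y = 0
        for r, h in enumerate(heights):
            x = 0
            for c, w in enumerate(widths):
                t = self.tiles[(r, c)]
                out[y : y + t.shape[0], x : x + t.shape[1]] = t
                x += w
            y += h
        return out

    # -- disk I/O ----------------------------------------------------------
    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (r, c), tile in self.tiles.items():
            tifffile.imwrite(directory / tile_name(r, c, (r, c) in self.truncated), tile)
        return directory

    @classmethod
    def load(cls, directory: str | Path, stage: str = "raw") -> "TileGrid":
        directory = Path(directory)
        tiles, truncated = {}, set()
        pat = re.compile(r"tile_r(\d+)_c(\d+)(_edge)?\.(tif|tiff|png|jpg|jpeg)$", re.I)
        for path in sorted(directory.iterdir()):
            m = pat.match(path.name)
            if not m:
                continue
            key = (int(m.group(1)), int(m.group(2)))
            if path.suffix.lower() in (".tif", ".tiff"):
                arr = tifffile.imread(path)
            else:
                arr = np.asarray(Image.open(path).convert("RGB"))
            tiles[key] = np.ascontiguousarray(arr[..., :3], dtype=np.uint8)
            if m.group(3):
                truncated.add(key)
        if not tiles:
            raise FileNotFoundError(f"no tiles found in {directory}")
        return cls(tiles=tiles, stage=stage, truncated=frozenset(truncated))


def split_small_tiles(grid: TileGrid, small_px: int = 360, allow_any_stage: bool = False) -> TileGrid:
    """Split medium tiles into small analysis tiles of ``small_px`` square.

    The default 360 px corresponds to roughly 100x100 um at the scanner pixel
    size.  Right/bottom remainders become truncated edge tiles flagged in
    their names; naming encodes the global small-tile row/col.
    """
    if grid.stage != "stainnormalized" and not allow_any_stage:
        raise ValueError(
            "expected a stain-normalized grid; pass allow_any_stage=True to override"
        )
    th, tw, _ = grid.tile_shape
    if small_px > min(th, tw):
        raise ValueError("small_px exceeds medium tile side")
    per_row = math.ceil(th / small_px)
    per_col = math.ceil(tw / small_px)
    out: dict[tuple[int, int], np.ndarray] = {}
    truncated = set()
    for (R, C), tile in grid.tiles.items():
        for i in range(per_row):
            for j in range(per_col):
                sub = tile[i * small_px : (i + 1) * small_px, j * small_px : (j + 1) * small_px]
                if sub.size == 0:
                    continue
                key = (R * per_row + i, C * per_col + j)
                out[key] = np.ascontiguousarray(sub)
                if sub.shape[0] != small_px or sub.shape[1] != small_px:
                    truncated.add(key)
    return TileGrid(tiles=out, stage="small", truncated=frozenset(truncated))


def make_overview(grid: TileGrid, downsample: int = 1, background_to_zero: bool = False) -> np.ndarray:
    """Stitched, subsampled montage; optionally zero the background sentinel.

    With ``background_to_zero`` the (255,255,255) sentinel pixels become
    black, producing the registration template with clear tissue contours.
    Output dims are ``ceil(total_px / downsample)`` per axis.
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    full = grid.stitch()
    over = full[::downsample, ::downsample].copy()
    if background_to_zero:
        over[np.all(over == 255, axis=-1)] = 0
    return over
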