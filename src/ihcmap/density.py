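"""Per-small-tile detection counts rendered as density maps.

Each processed small tile becomes one uniform 36x36-pixel block whose value
is the count of the histology measure inside that tile (cells, microglia,
or myelin-positive pixels), so the map resolution roughly matches the MRI
voxel grid.  Cells and microglia get a raw-count map plus a [0, 255]-scaled
display map; myelin gets only the scaled map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

BLOCK_PX = 36

KINDS = ("cell", "microglia", "myelin")


@dataclass
class DensityMap:
    values: np.ndarray       # (rows, cols) per-small-tile values
    kind: str
    scale: str               # 'raw' | 'scaled_0_255'
    image: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        vals = np.asarray(self.values)
        if self.scale == "raw":
            img = vals.astype(np.uint16)
        else:
            img = vals.astype(np.uint8)
        self.image = np.kron(img, np.ones((BLOCK_PX, BLOCK_PX), dtype=img.dtype))


def _scale_0_255(values: np.ndarray) -> np.ndarray:
    """round(255 * v / max), half-up; all-zero map stays zero."""
    vmax = values.max()
    if vmax == 0:
        return np.zeros_like(values, dtype=np.uint8)
    return np.floor(255.0 * values / vmax + 0.5).astype(np.uint8)


def counts_to_grid(counts: pd.DataFrame, n_rows: int | None = None,
                   n_cols: int | None = None) -> np.ndarray:
    """Pivot a per-tile count table (columns row, col, count) to a full 2D grid.

    Every (row, col) cell of the grid must be covered; missing entries are an
    error listing the offenders.
    """
    required = {"row", "col", "count"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    n_rows = n_rows if n_rows is not None else int(counts["row"].max()) + 1
    n_cols = n_cols if n_cols is not None else int(counts["col"].max()) + 1
    grid = np.full((n_rows, n_cols), -1, dtype=np.int64)
    for _, rec in counts.iterrows():
        grid[int(rec["row"]), int(rec["col"])] = int(rec["count"])
    missing = np.argwhere(grid < 0)
    if len(missing):
        listed = ", ".join(f"({r},{c})" for r, c in missing[:10])
        raise ValueError(f"missing tile entries in counts table: {listed}")
    return grid


def build_density_map(counts, kind: str) -> dict[str, DensityMap]:
    """Build the density map set for one detection kind.

    ``counts`` is either a full 2D array of per-small-tile values or a
    DataFrame with columns row/col/count covering the full grid.  Cells and
    microglia yield {'raw', 'scaled'}; myelin yields {'scaled'} only.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}")
    if isinstance(counts, pd.DataFrame):
        grid = counts_to_grid(counts)
    else:
        grid = np.asarray(counts, dtype=np.int64)
        if grid.ndim != 2:
            raise ValueError("counts array must be 2D")
    out = {"scaled": DensityMap(values=_scale_0_255(grid), kind=kind, scale="scaled_0_255")}
    if kind != "myelin":
        out["raw"] = DensityMap(values=grid, kind=kind, scale="raw")
    return out


def save_density_maps(maps: dict[str, DensityMap], directory: str | Path,
                      counts: np.ndarray | None = None) -> list[Path]:
    """Write raw maps as 16-bit TIFF, scaled maps as PNG, counts as CSV sidecar.

    Raw maps use 16 bits so true counts are never clipped at 255; truncated
    edge tiles render as full blocks (noted in the sidecar header).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, dm in maps.items():
        if dm.scale == "raw":
            p = directory / f"{dm.kind}_density_raw.tif"
            tifffile.imwrite(p, dm.image.astype(np.uint16))
        else:
            p = directory / f"{dm.kind}_density_scaled.png"
            Image.fromarray(dm.image.astype(np.uint8), mode="L").save(p)
        written.append(p)
    if counts is not None:
        rows, cols = np.indices(counts.shape)
        df = pd.DataFrame({"row": rows.ravel(), "col": cols.ravel(), "count": counts.ravel()})
        p = directory / f"{next(iter(maps.values())).kind}_counts.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written
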