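"""GPS-tagged harvest maps: grid the field, colour by representative size.

The mosaic is cut into fixed-size square grids (default 50 px, i.e. 1.5 m at
3 cm GSD — roughly a harvester working width); each detected head is assigned
to the grid containing its box centre, every grid gets per-class counts, a
representative (modal) size category and the GPS coordinate of its top-left
corner.  The grids drive the coloured harvest-region raster and the exported
per-grid statistics and 3D-chart table.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

from .io_georef import GeoRef, NDVIImage, pixel_to_gps
from .sizing import CATEGORIES, CATEGORY_COLOURS
from .synthetic_field import BOX

__all__ = [
    "HarvestGrid",
    "GridConfig",
    "grid_field",
    "representative_size",
    "render_harvest_map",
    "chart3d_data",
    "write_chart3d_csv",
]


@dataclass
class GridConfig:
    """Grid side length in pixels (>= 20 so at least one box fits)."""

    grid_size_px: int = 50

    def __post_init__(self) -> None:
        if self.grid_size_px < BOX:
            raise ValueError(f"grid size must be >= {BOX} px")


@dataclass
class HarvestGrid:
    row: int
    col: int
    corner_lat: float
    corner_lon: float
    n_small: int = 0
    n_medium: int = 0
    n_large: int = 0

    @property
    def total(self) -> int:
        return self.n_small + self.n_medium + self.n_large

    @property
    def representative(self) -> str | None:
        return representative_size(self)


def representative_size(grid: HarvestGrid) -> str | None:
    """Modal size category of a grid; ties go to the larger size.

    A grower planning selective harvest cares most about the largest
    marketable heads, hence the tie-break toward "large".  An empty grid has
    no representative and is left uncoloured.
    """
    counts = (grid.n_small, grid.n_medium, grid.n_large)
    if sum(counts) == 0:
        return None
    best = max(range(3), key=lambda i: (counts[i], i))
    return CATEGORIES[best]


def grid_field(img: NDVIImage, georef: GeoRef, records,
               cfg: GridConfig | None = None) -> list[HarvestGrid]:
    """Partition the field into grids and tally records by box centre.

    Produces ``ceil(height/g) x ceil(width/g)`` grids covering every pixel;
    each record lands in exactly one grid (the one containing its box
    centre), so grid counts conserve the record total.
    """
    cfg = cfg or GridConfig()
    g = cfg.grid_size_px
    n_rows = math.ceil(img.height / g)
    n_cols = math.ceil(img.width / g)
    grids = []
    for r in range(n_rows):
        for c in range(n_cols):
            lat, lon = pixel_to_gps(georef, c * g, r * g)
            grids.append(HarvestGrid(row=r, col=c, corner_lat=lat, corner_lon=lon))
    for rec in records:
        cx, cy = rec.centre
        r = min(int(cy // g), n_rows - 1)
        c = min(int(cx // g), n_cols - 1)
        grid = grids[r * n_cols + c]
        if rec.category == "small":
            grid.n_small += 1
        elif rec.category == "medium":
            grid.n_medium += 1
        else:
            grid.n_large += 1
    return grids


def render_harvest_map(grids, img_shape: tuple[int, int],
                       cfg: GridConfig | None = None) -> np.ndarray:
    """RGB raster of the harvest regions, same dimensions as the mosaic.

    Each grid cell is filled with its representative-category colour (blue
    small, green medium, red large); empty grids stay black.
    """
    cfg = cfg or GridConfig()
    g = cfg.grid_size_px
    h, w = img_shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for grid in grids:
        rep = representative_size(grid)
        if rep is None:
            continue
        y0, x0 = grid.row * g, grid.col * g
        out[y0:y0 + g, x0:x0 + g] = CATEGORY_COLOURS[rep]
    return out


def chart3d_data(grids) -> list[dict]:
    """Chart table: one record per non-empty grid.

    ``z`` (bar height) is the grid's total head count; ``category`` drives the
    bar colour; ``row``/``col`` are the in-field layout axes.
    """
    table = []
    for grid in grids:
        if grid.total == 0:
            continue
        table.append({"row": grid.row, "col": grid.col,
                      "total": grid.total,
                      "category": representative_size(grid)})
    return table


def write_chart3d_csv(table, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["row", "col", "total", "category"])
        for rec in table:
            w.writerow([rec["row"], rec["col"], rec["total"], rec["category"]])
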