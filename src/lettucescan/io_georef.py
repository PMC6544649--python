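"""Raster IO, pixel-to-GPS georeferencing and results export.

Pixel convention used throughout the package: 0-based indices, origin at the
image top-left, ``x`` is the column (increasing rightwards) and ``y`` the row
(increasing downwards).  Bounding boxes are half-open, ``[x, x+w) x [y, y+h)``.

GPS conversion uses the equirectangular small-field approximation: one degree
of latitude is taken as 111320 m and one degree of longitude as
``111320 * cos(lat0)`` m.  For fields of up to a few tens of hectares the
resulting error is far below one ground-sample distance, so no map projection
or datum handling is needed; the georeference always comes from user input
(top-left coordinate, rotation, GSD), never from embedded raster tags.
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

__all__ = [
    "METRES_PER_DEGREE_LAT",
    "NDVIImage",
    "GeoRef",
    "load_image",
    "save_image",
    "pixel_to_gps",
    "gps_to_pixel",
    "write_results_csv",
]

#: Metres per degree of latitude in the equirectangular approximation.
METRES_PER_DEGREE_LAT = 111320.0

#: Default ground-sample distance in metres per pixel (3 cm aerial imagery).
DEFAULT_GSD = 0.03


@dataclass
class NDVIImage:
    """A single-channel 8-bit NDVI raster.

    Brighter pixels correspond to stronger vegetation signal.  ``gsd`` is the
    ground-sample distance in metres per pixel.
    """

    pixels: np.ndarray
    gsd: float = DEFAULT_GSD

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"single-channel required, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GeoRef:
    """Georeference of a field mosaic.

    ``lat0``/``lon0`` locate the image's top-left pixel (decimal degrees).
    ``rotation_deg`` is the clockwise rotation of the image relative to a
    north-up orientation: at 0 the image +x axis points due east and +y due
    south; at rotation ``r`` every displacement is rotated ``r`` degrees
    clockwise in the east/north plane.
    """

    lat0: float
    lon0: float
    rotation_deg: float = 0.0
    gsd: float = DEFAULT_GSD

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat0 <= 90.0:
            raise ValueError("lat0 must lie in [-90, 90]")
        if not -180.0 <= self.lon0 <= 180.0:
            raise ValueError("lon0 must lie in [-180, 180]")
        self.rotation_deg = float(self.rotation_deg) % 360.0
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")


def load_image(path: str | os.PathLike, gsd: float = DEFAULT_GSD) -> NDVIImage:
    """Load a grey-level TIFF/PNG as an :class:`NDVIImage`.

    Multi-channel input is rejected rather than silently converted: the
    pipeline's intensity semantics (overflow correction, binning) are only
    defined for the single NDVI channel.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise ValueError(f"single-channel required, got shape {arr.shape}")
    return NDVIImage(arr, gsd=gsd)


def save_image(img: NDVIImage, path: str | os.PathLike) -> None:
    """Write the raster as 8-bit grey-level PNG or TIFF (by extension)."""
    iio.imwrite(path, img.pixels)


def _rotate_cw(east: float, north: float, deg: float) -> tuple[float, float]:
    """Rotate an (east, north) vector clockwise by ``deg`` degrees."""
    th = math.radians(deg)
    c, s = math.cos(th), math.sin(th)
    return east * c + north * s, north * c - east * s


def pixel_to_gps(g: GeoRef, x: float, y: float) -> tuple[float, float]:
    """Map a pixel coordinate to (lat, lon) decimal degrees.

    The displacement from the top-left pixel is ``(x*gsd, -y*gsd)`` metres in
    the image frame (y points down, hence the sign), rotated clockwise by
    ``rotation_deg`` into the east/north frame, and applied to ``(lat0, lon0)``
    equirectangularly.
    """
    east, north = _rotate_cw(x * g.gsd, -y * g.gsd, g.rotation_deg)
    lat = g.lat0 + north / METRES_PER_DEGREE_LAT
    lon = g.lon0 + east / (METRES_PER_DEGREE_LAT * math.cos(math.radians(g.lat0)))
    return lat, lon


def gps_to_pixel(g: GeoRef, lat: float, lon: float) -> tuple[float, float]:
    """Inverse of :func:`pixel_to_gps` on the same approximation."""
    north = (lat - g.lat0) * METRES_PER_DEGREE_LAT
    east = (lon - g.lon0) * METRES_PER_DEGREE_LAT * math.cos(math.radians(g.lat0))
    ex, ny = _rotate_cw(east, north, -g.rotation_deg)
    return ex / g.gsd, -ny / g.gsd


def write_results_csv(records, grids, path: str | os.PathLike) -> None:
    """Export per-field totals and per-grid harvest statistics as CSV.

    ``records`` are lettuce records carrying a ``category`` attribute
    (``small``/``medium``/``large``); ``grids`` are :class:`~lettucescan.harvest.HarvestGrid`
    cells.  The file starts with a field-summary block (total count and counts
    per size class), then one row per grid.  GPS values are printed with 7
    decimal places (~1 cm); the exported coordinate is the grid's top-left
    corner.
    """
    records = list(records)
    per_class = {"small": 0, "medium": 0, "large": 0}
    for r in records:
        per_class[r.category] += 1
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["total_count", "n_small", "n_medium", "n_large"])
        w.writerow([len(records), per_class["small"],
                    per_class["medium"], per_class["large"]])
        w.writerow([])
        w.writerow(["grid_row", "grid_col", "corner_lat", "corner_lon",
                    "n_small", "n_medium", "n_large", "representative_size"])
        for grd in grids:
            w.writerow([
                grd.row, grd.col,
                f"{grd.corner_lat:.7f}", f"{grd.corner_lon:.7f}",
                grd.n_small, grd.n_medium, grd.n_large,
                grd.representative if grd.representative is not None else "",
            ])
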