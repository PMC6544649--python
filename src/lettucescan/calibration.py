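"""Intensity calibration: overflow correction and CLAHE contrast enhancement.

NDVI sensors store a single 8-bit channel; over strongly vegetated pixels the
signal can exceed the sensor ceiling and wrap, so the brightest parts of a
lettuce head are recorded as near-black speckle.  ``correct_overflow`` repairs
those pixels before contrast-limited adaptive histogram equalisation (CLAHE)
stretches the lettuce/soil contrast that the classifier depends on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage import exposure

from .io_georef import NDVIImage

__all__ = ["CalibrationConfig", "correct_overflow", "apply_clahe", "calibrate"]


@dataclass
class CalibrationConfig:
    """Knobs for the calibration stage.

    ``overflow_dark_thresh``/``overflow_bright_thresh`` bracket the wrapped-
    highlight rule: a pixel darker than the dark threshold whose neighbourhood
    median is brighter than the bright threshold cannot be soil and is treated
    as a wrapped (saturated) value.  ``clahe_tile`` is the number of CLAHE
    tiles along each image axis (an 8x8 tile grid by default); ``clahe_clip``
    is the clip limit as a fraction of the per-tile histogram.
    """

    overflow_enabled: bool = True
    overflow_dark_thresh: int = 30
    overflow_bright_thresh: int = 200
    clahe_clip: float = 0.01
    clahe_tile: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.clahe_clip <= 1:
            raise ValueError("clahe_clip must lie in (0, 1]")
        if self.clahe_tile < 2:
            raise ValueError("clahe_tile must be >= 2")
        if self.overflow_dark_thresh >= self.overflow_bright_thresh:
            raise ValueError("dark threshold must be below bright threshold")


def correct_overflow(img: NDVIImage,
                     cfg: CalibrationConfig | None = None) -> NDVIImage:
    """Restore wrapped sensor-overflow pixels to full brightness.

    Rule: a pixel with intensity below ``overflow_dark_thresh`` whose
    8-neighbour median exceeds ``overflow_bright_thresh`` is a wrapped
    highlight, not soil, and is set to 255.  Because a wrapped core wider than
    a couple of pixels has wrapped neighbours of its own, the rule is iterated
    to a fixpoint, eating into the core from its bright rim; the fixpoint makes
    the operation idempotent.  Soil (dark pixels in dark neighbourhoods) is
    never touched.
    """
    cfg = cfg or CalibrationConfig()
    if not cfg.overflow_enabled:
        return NDVIImage(img.pixels.copy(), gsd=img.gsd)
    px = img.pixels.copy()
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    for _ in range(64):  # bound >> any plausible wrapped-core radius
        med = median_filter(px, footprint=footprint, mode="nearest")
        fix = (px < cfg.overflow_dark_thresh) & (med > cfg.overflow_bright_thresh)
        if not fix.any():
            break
        px[fix] = 255
    return NDVIImage(px, gsd=img.gsd)


def apply_clahe(img: NDVIImage,
                cfg: CalibrationConfig | None = None) -> NDVIImage:
    """Contrast-limited adaptive histogram equalisation on the 8-bit raster.

    The image is divided into a ``clahe_tile`` x ``clahe_tile`` grid of tiles,
    each histogram-equalised with clip limit ``clahe_clip``.  Output is mapped
    back to [0, 255]; the operation is deterministic and preserves dimensions.
    A constant image has a degenerate (delta) histogram and comes back
    constant.
    """
    cfg = cfg or CalibrationConfig()
    px = img.pixels
    if px.max() == px.min():
        return NDVIImage(px.copy(), gsd=img.gsd)
    kernel = (max(px.shape[0] // cfg.clahe_tile, 1),
              max(px.shape[1] // cfg.clahe_tile, 1))
    out = exposure.equalize_adapthist(px, kernel_size=kernel,
                                      clip_limit=cfg.clahe_clip)
    return NDVIImage(np.rint(out * 255).astype(np.uint8), gsd=img.gsd)


def calibrate(img: NDVIImage, cfg: CalibrationConfig | None = None) -> NDVIImage:
    """Full calibration stage: overflow correction (if enabled) then CLAHE."""
    cfg = cfg or CalibrationConfig()
    if cfg.overflow_enabled:
        img = correct_overflow(img, cfg)
    return apply_clahe(img, cfg)
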