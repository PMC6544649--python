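"""Synthetic NDVI lettuce fields with known ground truth.

Emulates the statistical structure of grey-level NDVI orthomosaics of iceberg
lettuce at pre-overlap head stages: rows of bright, roughly circular heads on
darker soil, three head-size classes whose blob area and peak brightness are
coupled (stronger NDVI response from bigger heads), a smooth regional
illumination gradient producing "very bright" and "very dark" zones, and
optional sensor-overflow pixels where a saturated bright value wraps around to
a near-black one.

Every generator is deterministic given ``FieldSpec.seed``.  Ground-truth head
centres and size classes are returned alongside the raster so that detection,
sizing and mapping can all be validated against a known answer.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io_georef import NDVIImage

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "LabelledPatch",
    "generate_field",
    "simulate_overflow",
    "generate_patch_dataset",
    "generate_localisation_patches",
    "write_truth_csv",
]

SIZE_CLASSES = ("small", "medium", "large")

#: Side of the bounding box that encloses a single head (pixels).
BOX = 20

#: Minimum distance (px) between a background patch centre and any head centre.
NEGATIVE_CLEARANCE = 15

#: Jitter (px) applied to positive patch centres, teaching translation tolerance.
POSITIVE_JITTER = 2


@dataclass
class FieldSpec:
    """Parameters of a synthetic field.

    Defaults describe a realistic 3 cm-GSD lettuce field: head radii of
    3-4 / 5-6 / 7-8 px per size class (all well inside a 20x20 box), soil at
    mean grey 80 with sd 8, per-class peak brightness increasing with size,
    a +-25 grey-level sinusoidal illumination field, and a minimum centre
    spacing of 12 px (~36 cm planting pitch).
    """

    height: int
    width: int
    n_lettuce: int
    class_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    radii: dict = field(default_factory=lambda: {
        "small": (3.0, 4.0), "medium": (5.0, 6.0), "large": (7.0, 8.0)})
    peak_intensity: dict = field(default_factory=lambda: {
        "small": (165.0, 190.0), "medium": (195.0, 225.0), "large": (225.0, 250.0)})
    soil_mean: float = 80.0
    soil_sd: float = 8.0
    gradient_amp: float = 25.0
    overflow: bool = False
    min_spacing: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if any(r[1] > 9 for r in self.radii.values()):
            raise ValueError("radii must be <= 9 px so a head fits a 20x20 box")
        if self.min_spacing <= 0:
            raise ValueError("min_spacing must be positive")

    @classmethod
    def for_count(cls, n_lettuce: int, **kwargs) -> "FieldSpec":
        """A square spec sized to hold ``n_lettuce`` heads at default packing."""
        spacing = kwargs.get("min_spacing", 12)
        pitch = spacing + 2
        # planted beds lose 2 of every 8 rows to tramlines; size up with slack
        side = int(math.ceil(math.sqrt(n_lettuce * 8 / 6) * pitch * 1.05)) \
            + 2 * _EDGE_MARGIN
        spec = cls(height=side, width=side, n_lettuce=n_lettuce, **kwargs)
        while _lattice_capacity(spec) < n_lettuce:
            side += pitch
            spec = cls(height=side, width=side, n_lettuce=n_lettuce, **kwargs)
        return spec


@dataclass
class GroundTruth:
    """Known head centres ``(x, y)`` and their size-class labels."""

    centres: np.ndarray          # (n, 2) float, columns x, y
    size_class: list             # n labels from SIZE_CLASSES

    def __len__(self) -> int:
        return len(self.size_class)


@dataclass
class LabelledPatch:
    """A 20x20 intensity patch with a binary head/background label."""

    pixels: np.ndarray
    label: int

    def __post_init__(self) -> None:
        if self.pixels.shape != (BOX, BOX):
            raise ValueError(f"patch must be {BOX}x{BOX}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


#: Unplanted border (headland) width in pixels.
_EDGE_MARGIN = 30

#: Of every _BED_PERIOD lattice rows, the last _TRAMLINE_ROWS are unplanted
#: (wheel tracks between beds), giving the field genuine soil corridors.
_BED_PERIOD = 8
_TRAMLINE_ROWS = 2


def _lattice_rows_cols(spec: FieldSpec) -> tuple[np.ndarray, np.ndarray]:
    pitch = spec.min_spacing + 2
    xs = np.arange(_EDGE_MARGIN, spec.width - _EDGE_MARGIN, pitch)
    ys_all = np.arange(_EDGE_MARGIN, spec.height - _EDGE_MARGIN, pitch)
    keep = np.arange(len(ys_all)) % _BED_PERIOD < _BED_PERIOD - _TRAMLINE_ROWS
    return xs, ys_all[keep]


def _lattice_capacity(spec: FieldSpec) -> int:
    xs, ys = _lattice_rows_cols(spec)
    return len(xs) * len(ys)


def _place_centres(spec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Row-lattice placement with +-1 px jitter.

    Pitch is ``min_spacing + 2`` so that after jitter every pair of centres is
    still at least ``min_spacing`` apart — verified, not assumed, before
    returning.
    """
    xs, ys = _lattice_rows_cols(spec)
    capacity = len(xs) * len(ys)
    if capacity < spec.n_lettuce:
        raise ValueError(
            f"infeasible packing: {spec.n_lettuce} heads requested but only "
            f"{capacity} lattice sites at spacing {spec.min_spacing}")
    gx, gy = np.meshgrid(xs, ys)
    sites = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    idx = rng.permutation(capacity)[: spec.n_lettuce]
    centres = sites[idx] + rng.uniform(-1.0, 1.0, size=(spec.n_lettuce, 2))
    if spec.n_lettuce > 1:
        tree = cKDTree(centres)
        pairs = tree.query_pairs(r=float(spec.min_spacing))
        if pairs:  # cannot happen with pitch >= spacing + 2, but never trust
            raise RuntimeError("packing violated min_spacing")
    return centres


def _preclip_field(spec: FieldSpec) -> tuple[np.ndarray, GroundTruth]:
    """Float field before clipping/wrapping, plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    img = rng.normal(spec.soil_mean, spec.soil_sd, size=(spec.height, spec.width))

    if spec.gradient_amp > 0:
        # Low-frequency diagonal sinusoid: ~1.5 periods across the field gives
        # distinct very-bright and very-dark regions in one raster.
        yy, xx = np.mgrid[0: spec.height, 0: spec.width]
        phase = 2 * np.pi * (1.5 * xx / max(spec.width, 1)
                             + 0.75 * yy / max(spec.height, 1))
        img += spec.gradient_amp * np.sin(phase)

    n = spec.n_lettuce
    if n == 0:
        return img, GroundTruth(np.empty((0, 2)), [])

    centres = _place_centres(spec, rng)
    labels = [SIZE_CLASSES[i] for i in
              rng.choice(3, size=n, p=np.asarray(spec.class_fractions))]
    for (cx, cy), cls in zip(centres, labels):
        r = rng.uniform(*spec.radii[cls])
        peak = rng.uniform(*spec.peak_intensity[cls])
        x0, x1 = int(cx - r - 1), int(cx + r + 2)
        y0, y1 = int(cy - r - 1), int(cy + r + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - cx, yy - cy)
        # Radial cosine: peak at the centre, back to soil level at radius r.
        prof = np.where(d < r, np.cos(0.5 * np.pi * d / r), 0.0)
        img[y0:y1, x0:x1] += (peak - spec.soil_mean) * prof
    return img, GroundTruth(centres, labels)


def generate_field(spec: FieldSpec) -> tuple[NDVIImage, GroundTruth]:
    """Render a synthetic field; wrap saturated pixels if ``spec.overflow``.

    The same seed with ``overflow`` toggled yields the identical field apart
    from the wrapped pixels, which is what makes the overflow-correction
    oracle possible.
    """
    pre, truth = _preclip_field(spec)
    if spec.overflow:
        img = simulate_overflow(pre, gsd=0.03)
    else:
        img = NDVIImage(np.clip(np.rint(pre), 0, 255).astype(np.uint8))
    return img, truth


def simulate_overflow(preclip: np.ndarray, threshold: float = 255.0,
                      gsd: float = 0.03) -> NDVIImage:
    """Wrap saturated intensities the way an 8-bit sensor overflow does.

    Pixels of the pre-clip float field above ``threshold`` are stored as
    ``value - 256`` (e.g. 300 -> 44), producing near-black cores inside the
    brightest heads; everything else is rounded and clipped to [0, 255].
    """
    if not 0 < threshold <= 255:
        raise ValueError("threshold must lie in (0, 255]")
    pre = np.asarray(preclip, dtype=float)
    out = np.clip(np.rint(pre), 0, 255)
    wrapped = pre > threshold
    out[wrapped] = np.clip(np.rint(pre[wrapped]) - 256, 0, 255)
    return NDVIImage(out.astype(np.uint8), gsd=gsd)


def generate_patch_dataset(img: NDVIImage, truth: GroundTruth, n: int,
                           seed: int = 0, return_positions: bool = False):
    """Balanced 20x20 labelled patches: heads versus soil/edges.

    ``n/2`` positives are centred on ground-truth heads with +-2 px jitter
    (several jittered copies per head are allowed when ``n/2`` exceeds the
    head count); ``n/2`` negatives are sampled at least 15 px away from every
    head centre.  Deterministic given ``seed``.
    """
    if n % 2:
        raise ValueError("n must be even (balanced classes)")
    if img.height <= BOX or img.width <= BOX:
        raise ValueError("image must be larger than the 20x20 box")
    half = n // 2
    n_heads = len(truth)
    max_jitter_copies = (2 * POSITIVE_JITTER + 1) ** 2
    if n_heads == 0 or half > n_heads * max_jitter_copies:
        raise ValueError("not enough distinct lettuces for the requested n")

    rng = np.random.default_rng(seed)
    px = img.pixels
    patches: list[LabelledPatch] = []
    positions: list[tuple[int, int]] = []

    # Positives: cycle through heads so each is used before any repeats.
    order = rng.permutation(n_heads)
    reps = int(np.ceil(half / n_heads))
    chosen = np.tile(order, reps)[:half]
    for i in chosen:
        cx, cy = truth.centres[i]
        jx, jy = rng.integers(-POSITIVE_JITTER, POSITIVE_JITTER + 1, size=2)
        x0 = int(round(cx)) - BOX // 2 + int(jx)
        y0 = int(round(cy)) - BOX // 2 + int(jy)
        x0 = min(max(x0, 0), img.width - BOX)
        y0 = min(max(y0, 0), img.height - BOX)
        patches.append(LabelledPatch(px[y0:y0 + BOX, x0:x0 + BOX].copy(), 1))
        positions.append((x0, y0))

    tree = cKDTree(truth.centres)
    got, attempts = 0, 0
    max_attempts = 200 * half
    while got < half:
        if attempts >= max_attempts:
            raise ValueError("not enough background area for the requested n")
        attempts += 1
        x0 = int(rng.integers(0, img.width - BOX + 1))
        y0 = int(rng.integers(0, img.height - BOX + 1))
        centre = (x0 + BOX / 2, y0 + BOX / 2)
        if tree.query(centre)[0] < NEGATIVE_CLEARANCE:
            continue
        patches.append(LabelledPatch(px[y0:y0 + BOX, x0:x0 + BOX].copy(), 0))
        positions.append((x0, y0))
        got += 1
    if return_positions:
        return patches, positions
    return patches


def generate_localisation_patches(img: NDVIImage, truth: GroundTruth, n: int,
                                  seed: int = 0,
                                  offset_range: tuple[float, float] = (6.0, 12.0),
                                  ) -> list[LabelledPatch]:
    """Balanced refinement patches that sharpen the classifier's localisation.

    A window that clips a head several pixels off-centre is *not* a box
    "enclosing a whole head", yet a model trained only on centred positives
    and far-away negatives happily scores it high — which floods the
    sliding-window detector with near-duplicate candidates that no overlap
    threshold can prune cleanly.  This generator produces ``n/2`` negatives
    whose box centre sits ``offset_range`` pixels from a head centre (label 0)
    and ``n/2`` fresh jittered positives (label 1), for use with the
    classifier's online-update retraining.
    """
    if n % 2:
        raise ValueError("n must be even (balanced classes)")
    if len(truth) == 0:
        raise ValueError("need at least one head")
    rng = np.random.default_rng(seed)
    px = img.pixels
    half = n // 2

    def clamp_box(x0: int, y0: int) -> tuple[int, int]:
        return (min(max(x0, 0), img.width - BOX),
                min(max(y0, 0), img.height - BOX))

    patches: list[LabelledPatch] = []
    heads = rng.integers(0, len(truth), size=half)
    angles = rng.uniform(0, 2 * np.pi, size=half)
    radii = rng.uniform(*offset_range, size=half)
    for i, ang, rad in zip(heads, angles, radii):
        cx, cy = truth.centres[i]
        x0, y0 = clamp_box(int(round(cx + rad * np.cos(ang))) - BOX // 2,
                           int(round(cy + rad * np.sin(ang))) - BOX // 2)
        patches.append(LabelledPatch(px[y0:y0 + BOX, x0:x0 + BOX].copy(), 0))
    heads = rng.integers(0, len(truth), size=half)
    for i in heads:
        cx, cy = truth.centres[i]
        jx, jy = rng.integers(-POSITIVE_JITTER, POSITIVE_JITTER + 1, size=2)
        x0, y0 = clamp_box(int(round(cx)) - BOX // 2 + int(jx),
                           int(round(cy)) - BOX // 2 + int(jy))
        patches.append(LabelledPatch(px[y0:y0 + BOX, x0:x0 + BOX].copy(), 1))
    return patches


def write_truth_csv(truth: GroundTruth, path) -> None:
    """Export ground truth as CSV rows (x, y, size_class)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "size_class"])
        for (x, y), cls in zip(truth.centres, truth.size_class):
            w.writerow([f"{x:.2f}", f"{y:.2f}", cls])
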