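"""Unsupervised size grading of detected heads: small / medium / large.

Each detected 20x20 box is summarised by an intensity histogram on geometric
bins that get finer toward 255: most soil lands in the first bins while the
bright high-NDVI pixels of a head spread over the fine top bins, so the
histogram's mass in high bins grows with head area and brightness.  The
histograms are clustered with k-means (k = 3) and the clusters are put into
size order by the dot product between each centroid and a non-decreasing
weight vector — low bins carry (near-)zero weight because dim surround pixels
say nothing about head size, high bins carry the largest weights.  The
smallest dot product is the "small" cluster, the largest is "large".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .io_georef import NDVIImage
from .synthetic_field import BOX

__all__ = [
    "DEFAULT_CUTOFFS",
    "CATEGORY_COLOURS",
    "BinScheme",
    "WeightVector",
    "LettuceRecord",
    "intensity_histogram",
    "cluster_sizes",
    "order_clusters",
    "categorise",
]

#: Geometric intensity cut-offs; bins are [0,64), [64,128), ... [253,254), [254,255].
DEFAULT_CUTOFFS = (64, 128, 160, 192, 208, 224, 232, 240, 244, 248, 250, 252,
                   253, 254)

CATEGORIES = ("small", "medium", "large")

#: Display colours (RGB) for rendered overlays.
CATEGORY_COLOURS = {"small": (0, 0, 255), "medium": (0, 255, 0),
                    "large": (255, 0, 0)}


@dataclass
class BinScheme:
    """Ascending intensity cut-offs defining len(cutoffs)+1 bins."""

    cutoffs: tuple = DEFAULT_CUTOFFS

    def __post_init__(self) -> None:
        c = np.asarray(self.cutoffs)
        if not np.all(np.diff(c) > 0):
            raise ValueError("cutoffs must be strictly ascending")
        if c[0] <= 0 or c[-1] >= 255:
            raise ValueError("cutoffs must lie strictly inside (0, 255)")

    @property
    def n_bins(self) -> int:
        return len(self.cutoffs) + 1


@dataclass
class WeightVector:
    """Non-decreasing, non-negative per-bin weights; default w_i = i."""

    weights: np.ndarray | None = None

    def for_bins(self, n_bins: int) -> np.ndarray:
        w = (np.arange(n_bins, dtype=float) if self.weights is None
             else np.asarray(self.weights, dtype=float))
        if len(w) != n_bins:
            raise ValueError(f"weight vector length {len(w)} != {n_bins} bins")
        if np.any(w < 0) or np.any(np.diff(w) < 0):
            raise ValueError("weights must be non-negative and non-decreasing")
        return w


@dataclass
class LettuceRecord:
    """A detected head with pixel position, probability and size category."""

    x: int
    y: int
    prob: float
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")

    @property
    def centre(self) -> tuple[float, float]:
        return (self.x + BOX / 2, self.y + BOX / 2)


def intensity_histogram(patch: np.ndarray,
                        scheme: BinScheme | None = None) -> np.ndarray:
    """Per-bin pixel counts of a 20x20 patch; counts always sum to 400."""
    scheme = scheme or BinScheme()
    patch = np.asarray(patch)
    if patch.shape != (BOX, BOX):
        raise ValueError(f"patch must be {BOX}x{BOX}, got {patch.shape}")
    edges = np.concatenate([[0], scheme.cutoffs, [256]])  # last bin closes at 255
    counts, _ = np.histogram(patch.ravel(), bins=edges)
    return counts


def cluster_sizes(histograms, k: int = 3, seed: int = 0):
    """K-means over raw histogram count vectors.

    Returns ``(labels, centroids)``; ``n_init=10`` seeded restarts, the best
    inertia kept.  Because every histogram sums to the same 400 pixels,
    clustering raw counts and relative frequencies are affinely equivalent.
    """
    H = np.asarray(histograms, dtype=float)
    if len(np.unique(H, axis=0)) < k:
        raise ValueError(f"fewer than k={k} distinct points")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(H)
    return labels, km.cluster_centers_


def order_clusters(centroids: np.ndarray,
                   weights: WeightVector | None = None) -> dict[int, str]:
    """Map cluster indices to size categories by weighted centroid mass.

    Clusters are sorted ascending by ``dot(weights, centroid)``; the smallest
    becomes "small", the middle "medium", the largest "large".  Ties break by
    cluster index, which makes the mapping deterministic.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[0] != 3:
        raise ValueError("exactly 3 centroids required")
    w = (weights or WeightVector()).for_bins(centroids.shape[1])
    scores = centroids @ w
    order = sorted(range(3), key=lambda i: (scores[i], i))
    return {cluster: CATEGORIES[rank] for rank, cluster in enumerate(order)}


def categorise(detections, img: NDVIImage, scheme: BinScheme | None = None,
               weights: WeightVector | None = None,
               seed: int = 0) -> list[LettuceRecord]:
    """Assign a size category to every detection box, preserving order.

    Histograms are taken from the image the detector saw (the calibrated
    mosaic).  With fewer than 3 detections no 3-cluster structure exists;
    everything is labelled "medium" with a warning.
    """
    detections = list(detections)
    scheme = scheme or BinScheme()
    if len(detections) < 3:
        warnings.warn("fewer than 3 detections: labelling all as 'medium'")
        return [LettuceRecord(d.x, d.y, d.prob, "medium") for d in detections]
    px = img.pixels
    hists = []
    for d in detections:
        x0 = min(max(d.x, 0), img.width - BOX)
        y0 = min(max(d.y, 0), img.height - BOX)
        hists.append(intensity_histogram(px[y0:y0 + BOX, x0:x0 + BOX], scheme))
    try:
        labels, centroids = cluster_sizes(hists, k=3, seed=seed)
    except ValueError:
        warnings.warn("histograms not separable into 3 clusters: all 'medium'")
        return [LettuceRecord(d.x, d.y, d.prob, "medium") for d in detections]
    mapping = order_clusters(centroids, weights)
    return [LettuceRecord(d.x, d.y, d.prob, mapping[int(lab)])
            for d, lab in zip(detections, labels)]
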