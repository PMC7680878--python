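"""Dominant-color clustering and nearest-centroid UPOV classification.

Ray-floret pixels are grouped into up to three k-means clusters on the
chroma (a8, b8) plane — lightness is deliberately ignored so that
ambient-illumination differences do not split a single petal color —
and every pixel is assigned to the UPOV category whose palette mean
vector is nearest in Euclidean distance.  The composition report gives
the per-category pixel percentages and the image's overall mean Lab8
vector (the "dominant color" dot of the scatter plots).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .colorspace import rgb_to_lab8
from .palette import CATEGORY_NAMES, ReferencePalette
from .segmentation import DegenerateInputWarning, SegmentationResult, segment_ray_florets

__all__ = [
    "ClusterResult",
    "CompositionReport",
    "cluster_dominant_colors",
    "classify_pixels",
    "composition_report",
    "classify_image",
    "is_multicolored",
]


@dataclass(frozen=True)
class ClusterResult:
    """k-means clustering of ray pixels on the (a8, b8) plane."""

    k_used: int
    labels: np.ndarray            # (N,) cluster id per pixel
    centers: np.ndarray           # (k_used, 2) cluster means in (a8, b8)
    dominant: tuple[int, ...]     # ids of the (up to) two largest clusters
    seed: int

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k_used)


@dataclass(frozen=True)
class CompositionReport:
    """Per-category composition of one flower's ray florets."""

    percentages: dict[str, float]       # category -> % of ray pixels
    mean_vector: np.ndarray | None      # (L8, a8, b8) over all ray pixels
    dominant_category: str | None
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels > 0:
            total = sum(self.percentages.values())
            if abs(total - 100.0) > 0.01:
                raise ValueError(f"percentages sum to {total}, expected 100")


def _merge_close_centers(
    labels: np.ndarray, centers: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Union clusters whose centers lie within ``radius`` of each other.

    k-means run with a fixed k splits a tight color blob into arbitrary
    halves; merging near-duplicate centers restores one cluster per
    actual color.  Merged centers are the size-weighted means.
    """
    k = centers.shape[0]
    parent = list(range(k))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(k):
        for j in range(i + 1, k):
            if np.linalg.norm(centers[i] - centers[j]) < radius:
                parent[find(j)] = find(i)
    roots = sorted({find(i) for i in range(k)})
    remap = {r: new for new, r in enumerate(roots)}
    group = np.array([remap[find(i)] for i in range(k)])
    new_labels = group[labels]
    sizes = np.bincount(labels, minlength=k).astype(np.float64)
    new_centers = np.zeros((len(roots), centers.shape[1]))
    for new in range(len(roots)):
        members = np.flatnonzero(group == new)
        w = sizes[members]
        new_centers[new] = (centers[members] * w[:, None]).sum(axis=0) / w.sum()
    return new_labels, new_centers


def cluster_dominant_colors(
    pixels: np.ndarray, k: int = 3, seed: int = 0, merge_radius: float = 8.0
) -> ClusterResult:
    """Cluster Lab8 pixels into up to ``k`` chroma clusters.

    Clustering runs on the (a8, b8) plane only.  The cluster count is
    reduced below ``k`` when the pixels contain fewer distinct chroma
    values, or when k-means returns centers closer than ``merge_radius``
    Lab8 units (a single tight color otherwise gets split into
    arbitrary halves).  Deterministic for a fixed ``seed``.

    Parameters
    ----------
    pixels : ndarray, shape (N, 3)
        Lab8 pixel values (e.g. ``lab8[seg.ray]``).
    merge_radius : float
        Centers closer than this are fused into one cluster; 0 disables
        merging.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2 or pixels.shape[1] != 3 or pixels.shape[0] == 0:
        raise ValueError("expected a nonempty (N, 3) array of Lab8 pixels")
    ab = pixels[:, 1:]
    n_distinct = np.unique(ab, axis=0).shape[0]
    k_used = min(k, n_distinct)
    km = KMeans(n_clusters=k_used, random_state=seed, n_init=10)
    labels = km.fit_predict(ab)
    centers = km.cluster_centers_
    if merge_radius > 0 and k_used > 1:
        labels, centers = _merge_close_centers(labels, centers, merge_radius)
        k_used = centers.shape[0]
    sizes = np.bincount(labels, minlength=k_used)
    order = np.argsort(-sizes, kind="stable")
    dominant = tuple(int(i) for i in order[: min(2, k_used)])
    return ClusterResult(
        k_used=k_used,
        labels=labels,
        centers=centers,
        dominant=dominant,
        seed=seed,
    )


def classify_pixels(
    pixels: np.ndarray, palette: ReferencePalette, use_L: bool = False
) -> np.ndarray:
    """Assign each Lab8 pixel to its nearest palette category.

    Distances are Euclidean on (a8, b8) by default; set ``use_L`` to
    include the lightness channel.  Ties go to the lowest category
    index.

    Returns
    -------
    ndarray of int, shape (N,)
        0-based category indices into :data:`CATEGORY_NAMES`.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2 or pixels.shape[1] != 3:
        raise ValueError("expected an (N, 3) array of Lab8 pixels")
    if use_L:
        pts, refs = pixels, palette.vectors()
    else:
        pts, refs = pixels[:, 1:], palette.ab_vectors()
    d = cdist(pts, refs)
    return np.argmin(d, axis=1)  # argmin takes the lowest index on ties


def composition_report(
    categories: np.ndarray, pixels: np.ndarray
) -> CompositionReport:
    """Summarize per-category pixel percentages and the mean Lab8 vector.

    ``percentage_c = 100 * count_c / n_pixels``; the dominant category is
    the argmax (lowest index on ties).
    """
    categories = np.asarray(categories)
    pixels = np.asarray(pixels, dtype=np.float64)
    n = categories.shape[0]
    if n == 0:
        raise ValueError("cannot build a composition report from zero pixels")
    if pixels.shape[0] != n:
        raise ValueError("categories and pixels must have equal length")
    counts = np.bincount(categories, minlength=len(CATEGORY_NAMES))
    pct = 100.0 * counts / n
    percentages = {name: float(p) for name, p in zip(CATEGORY_NAMES, pct)}
    return CompositionReport(
        percentages=percentages,
        mean_vector=pixels.mean(axis=0),
        dominant_category=CATEGORY_NAMES[int(np.argmax(counts))],
        n_pixels=int(n),
    )


def is_multicolored(report: CompositionReport, threshold: float = 20.0) -> bool:
    """Derived multicolor judgment: >= 2 categories above ``threshold`` %."""
    return sum(p >= threshold for p in report.percentages.values()) >= 2


def classify_image(
    img: np.ndarray,
    palette: ReferencePalette,
    k: int = 3,
    seed: int = 0,
    use_L: bool = False,
    **segment_kwargs: Any,
) -> tuple[CompositionReport, ClusterResult | None, SegmentationResult]:
    """End-to-end pipeline for a single flower photograph.

    Segments ray florets, clusters their pixels into dominant chroma
    clusters, classifies every pixel to its nearest palette category and
    reports the composition.  With an empty ray mask a degenerate report
    (zero pixels, no dominant category) is returned with a warning.
    """
    seg = segment_ray_florets(img, **segment_kwargs)
    if not seg.ray.any():
        warnings.warn(
            "no ray-floret pixels found; returning degenerate report",
            DegenerateInputWarning,
        )
        report = CompositionReport(
            percentages={n: 0.0 for n in CATEGORY_NAMES},
            mean_vector=None,
            dominant_category=None,
            n_pixels=0,
        )
        return report, None, seg
    lab8 = rgb_to_lab8(img)
    ray_pixels = lab8[seg.ray]
    clusters = cluster_dominant_colors(ray_pixels, k=k, seed=seed)
    cats = classify_pixels(ray_pixels, palette, use_L=use_L)
    report = composition_report(cats, ray_pixels)
    return report, clusters, seg
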