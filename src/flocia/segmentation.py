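"""Flower segmentation: background removal and disk-floret exclusion.

The acquisition protocol places a single flower head on a near-white
cloth, so the background is identified by low saturation and high value
in HSV.  Disk florets share hues with the surrounding ray florets but
have much finer texture, so they are removed by thresholding a local
standard-deviation ("texture energy") map computed after histogram
equalization, followed by morphological cleanup.  The remaining
foreground is the ray-floret mask used for color classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, filters, morphology

from .colorspace import rgb_to_hsv, hsv_gamut_filter

__all__ = [
    "SegmentationResult",
    "segment_foreground",
    "texture_energy_map",
    "segment_disk",
    "segment_ray_florets",
]


class DegenerateInputWarning(UserWarning):
    """Emitted when an image yields an empty segmentation mask."""


@dataclass(frozen=True)
class SegmentationResult:
    """Foreground, disk, and ray-floret masks for one image.

    Invariants (enforced at construction): ``disk`` is a subset of
    ``foreground`` and ``ray == foreground & ~disk``.
    """

    foreground: np.ndarray
    disk: np.ndarray
    ray: np.ndarray
    params_used: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.foreground.shape != self.disk.shape or self.disk.shape != self.ray.shape:
            raise ValueError("mask shapes must match")
        if np.any(self.disk & ~self.foreground):
            raise ValueError("disk mask must be a subset of the foreground")
        if np.any(self.ray != (self.foreground & ~self.disk)):
            raise ValueError("ray mask must equal foreground minus disk")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def segment_foreground(
    img: np.ndarray,
    white_thresh: float = 0.85,
    sat_thresh: float = 0.15,
) -> np.ndarray:
    """Separate the flower from a near-white backdrop.

    Background pixels are those with value >= ``white_thresh`` and
    saturation <= ``sat_thresh``; the complement is reduced to its
    largest connected component and hole-filled.

    Returns an empty mask (with a :class:`DegenerateInputWarning`) when
    nothing survives the filter, e.g. for an all-white image.
    """
    hsv = rgb_to_hsv(img)
    background = (hsv[..., 2] >= white_thresh) & (hsv[..., 1] <= sat_thresh)
    fg = ~background
    if not fg.any():
        warnings.warn("image is entirely background", DegenerateInputWarning)
        return fg
    fg = _largest_component(fg)
    return ndi.binary_fill_holes(fg)


def texture_energy_map(gray: np.ndarray, window: int = 5, equalize: bool = True) -> np.ndarray:
    """Local standard deviation, optionally after histogram equalization.

    With ``equalize=True`` (the default) the input is histogram-equalized
    before the population standard deviation over each
    ``window x window`` neighborhood is computed (reflection padding at
    the borders).  Rank equalization makes the map invariant to any
    monotone intensity transform, but it also caps a region's attainable
    local deviation by that region's area fraction; for amplitude-based
    thresholding of a small textured region pass ``equalize=False``
    (see :func:`segment_disk`).

    Parameters
    ----------
    gray : ndarray, 2-D single-channel image.
    window : odd int >= 3, neighborhood side length.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError("texture_energy_map expects a single-channel image")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if equalize:
        if gray.max() > gray.min():
            gray = exposure.equalize_hist(gray)
        else:
            gray = np.zeros_like(gray)
    mean = ndi.uniform_filter(gray, size=window, mode="reflect")
    mean_sq = ndi.uniform_filter(gray * gray, size=window, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var)


def segment_disk(
    img: np.ndarray,
    foreground: np.ndarray,
    window: int = 5,
    texture_thresh: float | None = None,
    morph_radius: int = 2,
) -> np.ndarray:
    """Locate the textured disk-floret region inside the foreground.

    Intensities are first normalized by percentile contrast stretching
    (2nd-98th), then the raw-amplitude texture map (local standard
    deviation, no rank equalization: a small disk could never dominate
    a rank-equalized map) is thresholded within the foreground — by
    Otsu's method by default, or at the quantile ``texture_thresh`` of
    foreground texture values if given — then cleaned by morphological
    closing and opening, reduced to the largest component, hole-filled,
    and eroded by half the filter window to undo the edge smear of the
    standard-deviation filter.

    Returns an empty mask when the flower has no high-texture region
    (e.g. a disk-free fixture).
    """
    foreground = np.asarray(foreground, dtype=bool)
    empty = np.zeros_like(foreground)
    if not foreground.any():
        return empty
    gray = np.asarray(img, dtype=np.float64)
    if gray.ndim == 3:
        gray = gray.mean(axis=2)
    lo, hi = np.percentile(gray, (2, 98))
    gray = exposure.rescale_intensity(gray, in_range=(lo, hi), out_range=(0.0, 1.0))
    tex = texture_energy_map(gray, window=window, equalize=False)
    tvals = tex[foreground]
    if texture_thresh is None:
        if np.ptp(tvals) == 0:
            return empty
        thresh = filters.threshold_otsu(tvals)
    else:
        if not 0.0 <= texture_thresh <= 1.0:
            raise ValueError("texture_thresh quantile must be in [0, 1]")
        thresh = float(np.quantile(tvals, texture_thresh))
    high = (tex > thresh) & foreground
    if not high.any():
        return empty
    selem = morphology.disk(morph_radius)
    high = morphology.closing(high, selem)
    high = morphology.opening(high, selem)
    if not high.any():
        return empty
    high = _largest_component(high)
    high = ndi.binary_fill_holes(high)
    # the std filter responds within window//2 pixels outside the true
    # textured region; erode to compensate
    high = morphology.erosion(high, morphology.disk(window // 2))
    return high & foreground


def segment_ray_florets(
    img: np.ndarray,
    white_thresh: float = 0.85,
    sat_thresh: float = 0.15,
    window: int = 5,
    texture_thresh: float | None = None,
    morph_radius: int = 2,
    apply_gamut: bool = False,
) -> SegmentationResult:
    """Full segmentation: foreground, disk, and ray-floret masks.

    ``ray = foreground & ~disk``; when ``apply_gamut`` is set the ray
    mask is further intersected with the yellow-red HSV gamut filter
    (which discards purple and other out-of-gamut petals — leave off for
    flowers outside the yellow-red range).
    """
    params = {
        "white_thresh": white_thresh,
        "sat_thresh": sat_thresh,
        "window": window,
        "texture_thresh": texture_thresh,
        "morph_radius": morph_radius,
        "apply_gamut": apply_gamut,
    }
    fg = segment_foreground(img, white_thresh=white_thresh, sat_thresh=sat_thresh)
    if not fg.any():
        empty = np.zeros_like(fg)
        return SegmentationResult(fg, empty, empty, params)
    disk = segment_disk(
        img, fg, window=window, texture_thresh=texture_thresh, morph_radius=morph_radius
    )
    ray = fg & ~disk
    if apply_gamut:
        hsv = rgb_to_hsv(img)
        ray = ray & hsv_gamut_filter(hsv, eval_mask=fg)
        fg = ray | disk
    if not ray.any():
        warnings.warn("ray-floret mask is empty", DegenerateInputWarning)
    return SegmentationResult(fg, disk, ray, params)
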