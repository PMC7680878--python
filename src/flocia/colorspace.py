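"""Color-space conversions and the HSV gamut filter.

All classification distances in this package are computed in an 8-bit
encoding of CIE L*a*b* ("Lab8"): ``L8 = L* * 255/100``, ``a8 = a* + 128``,
``b8 = b* + 128``, each clipped to [0, 255].  The offset encoding keeps
every channel on a common 0-255 scale, which is the convention most
image-processing toolboxes use when storing Lab in 8-bit buffers.
Conversions assume sRGB primaries with the IEC 61966-2-1 transfer
function and the D65 white point — the output of an ordinary consumer
camera.
"""

from __future__ import annotations

import numpy as np
from skimage import color as _skcolor

__all__ = [
    "rgb_to_lab8",
    "lab8_to_rgb",
    "rgb_to_hsv",
    "hsv_gamut_filter",
    "HUE_MIN_DEG",
    "HUE_MAX_DEG",
    "SAT_MIN_FRAC",
]

# Yellow-to-red hue gamut (degrees) retained by the ray-floret color filter,
# and the minimum saturation as a fraction of the maximum observed saturation.
HUE_MIN_DEG = 17.99
HUE_MAX_DEG = 66.95
SAT_MIN_FRAC = 0.125


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB image, got shape {img.shape!r}"
        )
    return img


def rgb_to_lab8(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit sRGB image to offset-encoded Lab8.

    Parameters
    ----------
    img : ndarray, shape (H, W, 3)
        sRGB image; uint8 in [0, 255] or float in [0, 1].

    Returns
    -------
    ndarray of float64, shape (H, W, 3)
        Channels ``(L8, a8, b8)``, each in [0, 255].  Neutral gray maps
        to ``a8 = b8 = 128``.
    """
    img = _check_rgb(img)
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / 255.0
    lab = _skcolor.rgb2lab(img)
    out = np.empty_like(lab)
    out[..., 0] = lab[..., 0] * (255.0 / 100.0)
    out[..., 1] = lab[..., 1] + 128.0
    out[..., 2] = lab[..., 2] + 128.0
    return np.clip(out, 0.0, 255.0)


def lab8_to_rgb(lab8: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_lab8`, returning a uint8 sRGB image.

    Out-of-gamut colors are clipped channelwise, so the round trip is
    exact only for colors inside the sRGB gamut.
    """
    lab8 = _check_rgb(lab8)
    lab = np.empty(lab8.shape, dtype=np.float64)
    lab[..., 0] = lab8[..., 0] * (100.0 / 255.0)
    lab[..., 1] = lab8[..., 1] - 128.0
    lab[..., 2] = lab8[..., 2] - 128.0
    rgb = _skcolor.lab2rgb(lab)
    return (np.clip(rgb, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert an sRGB image to hexcone HSV.

    Returns an (H, W, 3) float array with hue in degrees [0, 360) and
    saturation / value as fractions in [0, 1].
    """
    img = _check_rgb(img)
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(np.float64) / 255.0
    hsv = _skcolor.rgb2hsv(img)
    out = hsv.astype(np.float64, copy=True)
    out[..., 0] = (out[..., 0] * 360.0) % 360.0
    return out


def hsv_gamut_filter(
    hsv: np.ndarray,
    hue_min: float = HUE_MIN_DEG,
    hue_max: float = HUE_MAX_DEG,
    sat_min_frac: float = SAT_MIN_FRAC,
    eval_mask: np.ndarray | None = None,
    observed_smax: bool = True,
) -> np.ndarray:
    """Mask of pixels inside the yellow-red flower gamut.

    A pixel is kept when ``hue_min <= H <= hue_max`` and its saturation is
    at least ``sat_min_frac`` times the maximum saturation.  By default the
    maximum is taken over the evaluated pixels (all pixels, or those under
    ``eval_mask``), which is robust to exposure differences; pass
    ``observed_smax=False`` to use the theoretical maximum of 1.0.

    Parameters
    ----------
    hsv : ndarray, shape (H, W, 3)
        Output of :func:`rgb_to_hsv`.
    eval_mask : ndarray of bool, optional
        Restrict both the saturation maximum and the output to this region.

    Returns
    -------
    ndarray of bool, same (H, W) shape as the input.
    """
    hsv = _check_rgb(hsv)
    if hue_min > hue_max:
        raise ValueError(f"hue_min ({hue_min}) must not exceed hue_max ({hue_max})")
    h = hsv[..., 0]
    s = hsv[..., 1]
    if eval_mask is not None:
        eval_mask = np.asarray(eval_mask, dtype=bool)
        if eval_mask.shape != h.shape:
            raise ValueError("eval_mask shape must match the image")
    if observed_smax:
        s_eval = s[eval_mask] if eval_mask is not None else s
        s_max = float(s_eval.max()) if s_eval.size else 0.0
    else:
        s_max = 1.0
    keep = (h >= hue_min) & (h <= hue_max) & (s >= sat_min_frac * s_max)
    if eval_mask is not None:
        keep &= eval_mask
    return keep
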