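"""Resizing and specular-reflection removal.

Smartphone VIA images contain saturated specular highlights from the wet
cervix surface. Detection builds a single feature raster from three channels
in which highlights are jointly extreme — saturation S of HSV (inverted:
specular pixels are desaturated), green G of RGB, and lightness L of CIE-Lab
— then responds to their local contrast with a 3x3 standard-deviation filter
and min-max normalizes to [0, 1]. Removal thresholds that raster, dilates the
mask by one pixel, and inpaints from the mask boundary inward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_fill_holes, correlate, uniform_filter
from skimage.color import rgb2hsv, rgb2lab
from skimage.transform import resize

__all__ = [
    "SpecularResult",
    "resize_image",
    "stddev_filter",
    "specular_feature_image",
    "remove_specular",
]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class SpecularResult:
    """Specular detection/removal output.

    ``cleaned`` equals the input everywhere outside ``specular_mask``.
    """

    feature_image: np.ndarray  # H x W float in [0, 1]
    specular_mask: np.ndarray  # H x W bool (thresholded + 1-px dilation)
    cleaned: np.ndarray  # H x W x 3 uint8


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"image must be at least 3 x 3, got {img.shape[:2]}")
    return img


def resize_image(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize to ``size`` = (height, width), preserving uint8 range."""
    img = _check_rgb(img)
    h, w = size
    if h < 3 or w < 3:
        raise ValueError(f"target size must be at least 3 x 3, got {size}")
    if img.shape[:2] == (h, w):
        return img.copy()
    out = resize(img.astype(np.float64), (h, w), order=1, mode="edge", anti_aliasing=False)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def stddev_filter(raster: np.ndarray, window: int = 3) -> np.ndarray:
    """Population standard deviation over a window x window neighborhood.

    Borders are handled by edge replication.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    x = np.asarray(raster, dtype=np.float64)
    mean = uniform_filter(x, size=window, mode="nearest")
    mean_sq = uniform_filter(x * x, size=window, mode="nearest")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var)


def _minmax01(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi - lo < 1e-12:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


#: lower edge of the jointly-bright tail kept by the soft emphasis; tissue sits
#: well below it (cervix ~0.5, background lower) while specular pixels approach 1
_EMPHASIS_FLOOR = 0.7


def specular_feature_image(img: np.ndarray) -> np.ndarray:
    """Specular-response raster in [0, 1].

    Per-channel min-max normalizes inverted-S, G and L to [0, 1] and averages
    them; specular pixels are jointly extreme in all three, so a soft emphasis
    then rescales the [0.7, 1] tail to [0, 1] and zeroes the tissue range —
    without it, ordinary image noise produces a floor of filter response
    everywhere and drowns the highlight signal. The 3x3 standard-deviation
    filter and a final min-max normalization produce the response raster.
    A constant input maps to an all-zero raster.
    """
    img = _check_rgb(img)
    rgb01 = img.astype(np.float64) / 255.0
    s_inv = 1.0 - rgb2hsv(rgb01)[..., 1]
    g = rgb01[..., 1]
    lightness = rgb2lab(rgb01)[..., 0] / 100.0
    combined = (_minmax01(s_inv) + _minmax01(g) + _minmax01(lightness)) / 3.0
    emphasized = np.clip((combined - _EMPHASIS_FLOOR) / (1.0 - _EMPHASIS_FLOOR), 0.0, 1.0)
    return _minmax01(stddev_filter(emphasized, window=3))


def _inpaint_boundary_mean(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill masked pixels layer by layer with the mean of known 8-neighbors."""
    filled = img.astype(np.float64).copy()
    remaining = mask.copy()
    kernel = _EIGHT_CONN.astype(np.float64)
    while remaining.any():
        known = ~remaining
        n_known = correlate(known.astype(np.float64), kernel, mode="constant")
        boundary = remaining & (n_known > 0)
        if not boundary.any():  # mask covers the whole image: nothing to copy from
            break
        for c in range(img.shape[2]):
            acc = correlate(np.where(known, filled[..., c], 0.0), kernel, mode="constant")
            filled[boundary, c] = acc[boundary] / n_known[boundary]
        remaining &= ~boundary
    return np.clip(np.rint(filled), 0, 255).astype(np.uint8)


def remove_specular(img: np.ndarray, threshold: float = 0.5) -> SpecularResult:
    """Detect and inpaint specular highlights.

    ``specular_mask`` is feature response > ``threshold``, dilated by one
    pixel and hole-filled (the std-dev filter responds on the highlight rim,
    so the interior of a glint is recovered by closing the ring); masked
    pixels are replaced by boundary-mean inpainting.
    """
    img = _check_rgb(img)
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    feat = specular_feature_image(img)
    mask = binary_fill_holes(binary_dilation(feat > threshold, structure=_EIGHT_CONN))
    cleaned = _inpaint_boundary_mean(img, mask) if mask.any() else img.copy()
    return SpecularResult(feature_image=feat, specular_mask=mask, cleaned=cleaned)
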