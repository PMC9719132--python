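"""Cervix region-of-interest detection.

The cervix sits near the frame center and is redder than the surround, so a
two-component Gaussian mixture over the per-pixel pair (R, a*) — R the
Euclidean distance from the image center in pixels, a* the CIE-Lab red-green
channel — separates cervix from background. Spherical covariances (after
joint standardization of the two features) encourage a compact, disk-like
component; the most central component (smallest mean R) is taken as cervix,
reduced to its largest connected region with holes filled. The ROI is then
cropped with 5% padding and zoomed back to the 200x200 working resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.color import rgb2lab
from skimage.measure import label as cc_label
from skimage.transform import resize
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from viascreen.errors import EmptyMaskError, RoiConvergenceError
from viascreen.preprocessing import resize_image

__all__ = ["RaSpace", "RoiResult", "to_ra_space", "fit_roi_gmm", "crop_and_zoom", "detect_roi"]


@dataclass
class RaSpace:
    """Per-pixel (R, a*) features; R >= 0 with R = 0 at the image center."""

    R: np.ndarray  # H x W float, distance from center in pixels
    a: np.ndarray  # H x W float, CIE-Lab a*


@dataclass
class RoiResult:
    mask: np.ndarray  # H x W bool, largest component, holes filled
    center: tuple[float, float]  # (row, col) centroid of the mask
    radius: float  # equivalent-disk radius in pixels
    crop: np.ndarray | None = None  # 200 x 200 x 3 uint8 zoomed ROI
    crop_mask: np.ndarray | None = None  # 200 x 200 bool, mask carried forward


def to_ra_space(img: np.ndarray) -> RaSpace:
    """Compute the (R, a*) rasters; image center is ((H-1)/2, (W-1)/2)."""
    img = np.asarray(img)
    h, w = img.shape[:2]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r = np.hypot(yy - cy, xx - cx)
    a = rgb2lab(img.astype(np.float64) / 255.0)[..., 1]
    return RaSpace(R=r, a=a)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 1e-12 else 1.0)


def fit_roi_gmm(
    ra: RaSpace,
    n_components: int = 2,
    seed: int = 0,
    geometric_disk: bool = False,
) -> RoiResult:
    """Fit the spherical GMM on standardized (R, a*) and extract the cervix mask.

    K-means initialization (10 restarts, best inertia, seeded); the cervix
    component is the one with smallest mean R, ties broken by larger mean a*.
    With ``geometric_disk`` the mask is replaced by the equivalent disk at the
    mask centroid.
    """
    if n_components < 2:
        raise ValueError(f"n_components must be >= 2, got {n_components}")
    h, w = ra.R.shape
    feats = np.column_stack([_standardize(ra.R).ravel(), _standardize(ra.a).ravel()])
    km = KMeans(n_clusters=n_components, n_init=10, random_state=seed).fit(feats)
    gmm = GaussianMixture(
        n_components=n_components,
        covariance_type="spherical",
        means_init=km.cluster_centers_,
        random_state=seed,
        max_iter=200,
    )
    assign = gmm.fit_predict(feats)
    if not gmm.converged_:
        raise RoiConvergenceError(gmm.n_iter_)

    mean_r = np.array([ra.R.ravel()[assign == k].mean() if (assign == k).any() else np.inf
                       for k in range(n_components)])
    mean_a = np.array([ra.a.ravel()[assign == k].mean() if (assign == k).any() else -np.inf
                       for k in range(n_components)])
    # smallest mean R wins; exact ties go to the redder component
    order = np.lexsort((-mean_a, mean_r))
    cervix = order[0]

    mask = (assign == cervix).reshape(h, w)
    labels = cc_label(mask, connectivity=2)
    if labels.max() > 0:
        sizes = np.bincount(labels.ravel())[1:]
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = binary_fill_holes(mask)

    ys, xs = np.nonzero(mask)
    center = (float(ys.mean()), float(xs.mean()))
    radius = float(np.sqrt(mask.sum() / np.pi))
    if geometric_disk:
        yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
        mask = np.hypot(yy - center[0], xx - center[1]) <= radius
    return RoiResult(mask=mask, center=center, radius=radius)


def crop_and_zoom(
    img: np.ndarray, mask: np.ndarray, size: tuple[int, int] = (200, 200)
) -> tuple[np.ndarray, np.ndarray]:
    """Crop the mask's padded bounding box and zoom to ``size``.

    The bounding box is expanded by 5% of its height/width on each side and
    clipped to the image. The image is resized bilinearly, the mask by
    nearest neighbor; both are returned.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("ROI mask is empty; fall back to a whole-image ROI")
    ys, xs = np.nonzero(mask)
    r0, r1 = int(ys.min()), int(ys.max()) + 1
    c0, c1 = int(xs.min()), int(xs.max()) + 1
    pad_r = int(round(0.05 * (r1 - r0)))
    pad_c = int(round(0.05 * (c1 - c0)))
    r0, r1 = max(r0 - pad_r, 0), min(r1 + pad_r, img.shape[0])
    c0, c1 = max(c0 - pad_c, 0), min(c1 + pad_c, img.shape[1])
    crop = resize_image(img[r0:r1, c0:c1], size)
    crop_mask = resize(
        mask[r0:r1, c0:c1].astype(np.float64), size, order=0, mode="edge", anti_aliasing=False
    ) > 0.5
    return crop, crop_mask


def detect_roi(img: np.ndarray, seed: int = 0, n_components: int = 2) -> RoiResult:
    """Full ROI stage: (R, a*) features, GMM mask, padded crop and zoom."""
    result = fit_roi_gmm(to_ra_space(img), n_components=n_components, seed=seed)
    result.crop, result.crop_mask = crop_and_zoom(img, result.mask)
    return result
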