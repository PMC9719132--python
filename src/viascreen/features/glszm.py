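"""Gray-level size-zone matrix features.

A zone is an 8-connected component of equal quantized gray level inside the
mask. P(g, s) counts zones of level g and size s; fourteen statistics
summarize the matrix. Gray levels enter the emphasis formulas 1-based.
"""

from __future__ import annotations

import numpy as np
from skimage.measure import label as cc_label

__all__ = ["GLSZM_NAMES", "glszm_matrix", "glszm_features"]

GLSZM_NAMES = [
    "glszm_small_zone_emphasis",
    "glszm_large_zone_emphasis",
    "glszm_gray_level_nonuniformity",
    "glszm_gray_level_nonuniformity_normalized",
    "glszm_size_zone_nonuniformity",
    "glszm_zone_percentage",
    "glszm_low_gray_level_zone_emphasis",
    "glszm_high_gray_level_zone_emphasis",
    "glszm_small_zone_low_gray_level_emphasis",
    "glszm_small_zone_high_gray_level_emphasis",
    "glszm_large_zone_low_gray_level_emphasis",
    "glszm_large_zone_high_gray_level_emphasis",
    "glszm_gray_level_variance",
    "glszm_zone_size_variance",
]


def glszm_matrix(gray: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """P(g, s): levels x max_zone_size matrix of zone counts."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    n_px = int(mask.sum())
    p = np.zeros((levels, n_px), dtype=np.float64)
    for g in range(levels):
        region = mask & (np.asarray(gray) == g)
        if not region.any():
            continue
        labels = cc_label(region, connectivity=2)
        sizes = np.bincount(labels.ravel())[1:]
        for size in sizes:
            p[g, size - 1] += 1.0
    return p


def glszm_features(gray: np.ndarray, mask: np.ndarray, levels: int) -> dict[str, float]:
    p = glszm_matrix(gray, mask, levels)
    nz = float(p.sum())  # number of zones
    n_px = float(np.asarray(mask, dtype=bool).sum())
    g = np.arange(1, levels + 1, dtype=np.float64)[:, None]  # 1-based level
    s = np.arange(1, p.shape[1] + 1, dtype=np.float64)[None, :]  # zone size

    pg = p.sum(axis=1)  # zones per gray level
    ps = p.sum(axis=0)  # zones per size
    prob = p / nz
    mu_g = float((g[:, 0] * prob.sum(axis=1)).sum())
    mu_s = float((s[0, :] * prob.sum(axis=0)).sum())

    return {
        "glszm_small_zone_emphasis": float((p / s**2).sum() / nz),
        "glszm_large_zone_emphasis": float((p * s**2).sum() / nz),
        "glszm_gray_level_nonuniformity": float((pg**2).sum() / nz),
        "glszm_gray_level_nonuniformity_normalized": float((pg**2).sum() / nz**2),
        "glszm_size_zone_nonuniformity": float((ps**2).sum() / nz),
        "glszm_zone_percentage": float(nz / n_px),
        "glszm_low_gray_level_zone_emphasis": float((p / g**2).sum() / nz),
        "glszm_high_gray_level_zone_emphasis": float((p * g**2).sum() / nz),
        "glszm_small_zone_low_gray_level_emphasis": float((p / (g**2 * s**2)).sum() / nz),
        "glszm_small_zone_high_gray_level_emphasis": float((p * g**2 / s**2).sum() / nz),
        "glszm_large_zone_low_gray_level_emphasis": float((p * s**2 / g**2).sum() / nz),
        "glszm_large_zone_high_gray_level_emphasis": float((p * g**2 * s**2).sum() / nz),
        "glszm_gray_level_variance": float((prob * (g - mu_g) ** 2).sum()),
        "glszm_zone_size_variance": float((prob * (s - mu_s) ** 2).sum()),
    }
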