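"""Neighbourhood gray-tone difference matrix (Amadasun-King) features.

For each masked pixel that has at least one masked 8-neighbor, the absolute
difference between its gray level and the mean of its masked neighbors is
accumulated per level (s_i); level occupancy gives p_i. Gray levels enter
the formulas 1-based so that the lowest level carries weight. The five
descriptors are coarseness, contrast, busyness, complexity and strength.

Limiting conventions: a region with no gray-tone differences (sum of s_i = 0)
has coarseness capped at 1e6 and busyness/strength 0; contrast is 0 when
fewer than two gray levels are present.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate

__all__ = ["NGTDM_NAMES", "COARSENESS_CAP", "ngtdm_table", "ngtdm_features"]

NGTDM_NAMES = [
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
]

COARSENESS_CAP = 1e6
_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.float64)


def ngtdm_table(gray: np.ndarray, mask: np.ndarray, levels: int):
    """Return (s, p, n_valid): per-level difference sums, probabilities, pixel count."""
    mask = np.asarray(mask, dtype=bool)
    g = np.asarray(gray, dtype=np.float64)
    n_neigh = correlate(mask.astype(np.float64), _NEIGH, mode="constant")
    neigh_sum = correlate(np.where(mask, g, 0.0), _NEIGH, mode="constant")
    valid = mask & (n_neigh > 0)
    if not valid.any():
        raise ValueError("mask has no pixel with an in-mask neighbor")
    diff = np.abs(g - neigh_sum / np.maximum(n_neigh, 1.0))
    s = np.zeros(levels)
    counts = np.zeros(levels)
    lv = gray[valid].astype(int)
    np.add.at(s, lv, diff[valid])
    np.add.at(counts, lv, 1.0)
    n_valid = int(valid.sum())
    return s, counts / n_valid, n_valid


def ngtdm_features(gray: np.ndarray, mask: np.ndarray, levels: int) -> dict[str, float]:
    s, p, n = ngtdm_table(gray, mask, levels)
    present = p > 0
    ngp = int(present.sum())
    lv = np.arange(1, levels + 1, dtype=np.float64)  # 1-based intensities

    psum = float((p * s).sum())
    coarseness = min(1.0 / psum, COARSENESS_CAP) if psum > 1e-12 else COARSENESS_CAP

    if ngp < 2:
        contrast = 0.0
    else:
        pi, pj = np.meshgrid(p, p, indexing="ij")
        li, lj = np.meshgrid(lv, lv, indexing="ij")
        contrast = float(
            (pi * pj * (li - lj) ** 2).sum() / (ngp * (ngp - 1)) * (s.sum() / n)
        )

    ip = lv * p
    act = np.ix_(present, present)
    pi, pj = np.meshgrid(p, p, indexing="ij")
    li, lj = np.meshgrid(lv, lv, indexing="ij")
    si, sj = np.meshgrid(s, s, indexing="ij")
    ipi, ipj = np.meshgrid(ip, ip, indexing="ij")

    busy_denom = float(np.abs(ipi[act] - ipj[act]).sum())
    busyness = float(psum / busy_denom) if busy_denom > 1e-12 else 0.0

    complexity = float(
        (np.abs(li[act] - lj[act]) * (pi[act] * si[act] + pj[act] * sj[act])
         / (n * (pi[act] + pj[act]))).sum()
    )

    s_total = float(s.sum())
    strength = (
        float(((pi[act] + pj[act]) * (li[act] - lj[act]) ** 2).sum() / s_total)
        if s_total > 1e-12
        else 0.0
    )

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }
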