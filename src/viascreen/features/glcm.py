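"""Gray-level co-occurrence matrix features.

Symmetric, normalized co-occurrence matrices at distance 1 in the four
standard directions (0, 45, 90, 135 degrees), with pairs counted only when
both pixels lie inside the mask. Fourteen Haralick statistics are computed
per direction; the panel stores their mean and range over directions,
giving 28 values.

Degenerate-case conventions (documented because several Haralick statistics
are undefined on a single-gray-level region): correlation and the maximal
correlation coefficient are 1 when a marginal is concentrated on one level;
information measures of correlation fall back to 0 when their denominators
vanish. Logarithms are natural; zero probabilities contribute zero entropy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["HARALICK_NAMES", "GLCM_NAMES", "glcm_matrices", "haralick_stats", "glcm_features"]

# (dr, dc) offsets for 0, 45, 90, 135 degrees in image coordinates
_OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]

HARALICK_NAMES = [
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
    "mcc",
]

GLCM_NAMES = [f"glcm_{stat}_{agg}" for stat in HARALICK_NAMES for agg in ("mean", "range")]


def glcm_matrices(gray: np.ndarray, mask: np.ndarray, levels: int) -> list[np.ndarray]:
    """Normalized symmetric co-occurrence matrix per direction.

    Raises if no direction yields a valid in-mask pixel pair.
    """
    gray = np.asarray(gray)
    mask = np.asarray(mask, dtype=bool)
    mats = []
    any_pairs = False
    for dr, dc in _OFFSETS:
        p = np.zeros((levels, levels), dtype=np.float64)
        h, w = gray.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = gray[r0:r1, c0:c1]
        b = gray[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if valid.any():
            np.add.at(p, (a[valid], b[valid]), 1.0)
            p = p + p.T  # symmetric
            p /= p.sum()
            any_pairs = True
        mats.append(p)
    if not any_pairs:
        raise ValueError("mask contains no valid pixel pair for any GLCM direction")
    return mats


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def haralick_stats(p: np.ndarray) -> dict[str, float]:
    """The 14 Haralick statistics of one normalized symmetric GLCM."""
    levels = p.shape[0]
    i = np.arange(levels, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    p_sum = np.zeros(2 * levels - 1)
    p_diff = np.zeros(levels)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * levels - 1, dtype=np.float64)
    k_diff = np.arange(levels, dtype=np.float64)

    out: dict[str, float] = {}
    out["asm"] = float((p * p).sum())
    out["contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sd_x * sd_y > 1e-12:
        out["correlation"] = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        out["correlation"] = 1.0
    out["variance"] = float(((ii - mu_x) ** 2 * p).sum())
    out["idm"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    out["sum_average"] = sum_avg
    out["sum_variance"] = float(((k_sum - sum_avg) ** 2 * p_sum).sum())
    out["sum_entropy"] = _entropy(p_sum)
    hxy = _entropy(p)
    out["entropy"] = hxy
    diff_avg = float((k_diff * p_diff).sum())
    out["difference_variance"] = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    out["difference_entropy"] = _entropy(p_diff)

    # information measures of correlation
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        log_pxy = np.where(pxy > 0, np.log(pxy), 0.0)
    hxy1 = float(-(p * log_pxy).sum())
    hxy2 = float(-(pxy * log_pxy).sum())
    hx, hy = _entropy(px), _entropy(py)
    denom = max(hx, hy)
    out["imc1"] = float((hxy - hxy1) / denom) if denom > 1e-12 else 0.0
    out["imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # maximal correlation coefficient: sqrt of the second largest eigenvalue of Q
    active = px > 0
    if active.sum() < 2:
        out["mcc"] = 1.0
    else:
        pa = p[np.ix_(active, active)]
        px_a, py_a = px[active], py[active]
        q = (pa / px_a[:, None]) @ (pa / py_a[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        out["mcc"] = float(np.sqrt(max(0.0, eig[-2])))
    return out


def glcm_features(gray: np.ndarray, mask: np.ndarray, levels: int) -> dict[str, float]:
    """Mean and range over the four directions of each Haralick statistic."""
    # a direction can lack in-mask pairs on sliver masks; aggregate over the rest
    per_dir = [haralick_stats(p) for p in glcm_matrices(gray, mask, levels) if p.sum() > 0]
    out: dict[str, float] = {}
    for stat in HARALICK_NAMES:
        vals = np.array([d[stat] for d in per_dir])
        out[f"glcm_{stat}_mean"] = float(vals.mean())
        out[f"glcm_{stat}_range"] = float(vals.max() - vals.min())
    return out
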