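"""Uniform local binary pattern histogram (P=8, R=1).

The uniform encoding assigns each pixel the number of set bits of its
8-neighbor comparison code when the circular code has at most two 0-1
transitions (9 bins, 0..8) and a single overflow bin for non-uniform codes,
giving a 10-bin histogram normalized over the masked pixels.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import local_binary_pattern

__all__ = ["LBP_NAMES", "lbp_features"]

LBP_NAMES = [f"lbp_u8r1_bin{i}" for i in range(10)]


def lbp_features(gray: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    codes = local_binary_pattern(
        np.rint(np.asarray(gray, dtype=np.float64)).astype(np.uint8), P=8, R=1, method="uniform"
    )
    # pixels on the image frame see phantom zero neighbors; keep only pixels
    # with a complete circular neighborhood (fall back to all masked pixels
    # for rasters too small to have an interior)
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = mask[1:-1, 1:-1]
    if not interior.any():
        interior = mask
    hist = np.bincount(codes[interior].astype(int), minlength=10).astype(np.float64)
    hist /= hist.sum()
    return {name: float(v) for name, v in zip(LBP_NAMES, hist)}
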