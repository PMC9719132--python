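"""Single-level 2-D discrete wavelet transform features.

Pixels outside the mask are replaced by the masked mean before the transform
so edge energy at the mask boundary does not leak into the statistics. The
six values are the mean and population standard deviation of the absolute
detail coefficients in the LH, HL and HH subbands. Subband orientation is
pinned so that HL responds to vertical edges (intensity varying along x).
"""

from __future__ import annotations

import numpy as np
import pywt

__all__ = ["DWT_NAMES", "dwt_features"]

DWT_NAMES = [f"dwt_{band}_{stat}" for band in ("LH", "HL", "HH") for stat in ("mean", "std")]


def dwt_features(
    gray: np.ndarray, mask: np.ndarray, wavelet: str = "haar"
) -> dict[str, float]:
    g = np.asarray(gray, dtype=np.float64)
    if g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError(f"crop must be at least 2 x 2 for the DWT, got {g.shape}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    filled = np.where(mask, g, g[mask].mean())
    _, (c_h, c_v, c_d) = pywt.dwt2(filled, wavelet)
    # pywt's cV detail carries vertical-edge energy -> HL by our naming
    bands = {"LH": c_h, "HL": c_v, "HH": c_d}
    out: dict[str, float] = {}
    for name, coef in bands.items():
        a = np.abs(coef)
        out[f"dwt_{name}_mean"] = float(a.mean())
        out[f"dwt_{name}_std"] = float(a.std())
    return out
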