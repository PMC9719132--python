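"""Color statistics over the masked ROI.

Mean and population standard deviation of R, G, B, the per-pixel ratios
G/(R+1) and B/(R+1) (the +1 on 8-bit values guards division by zero, which
the feature names record), and the HSV value channel V = max(R,G,B)/255.
"""

from __future__ import annotations

import numpy as np

__all__ = ["COLOR_NAMES", "MIN_MASK_PIXELS", "color_features"]

MIN_MASK_PIXELS = 64

_CHANNELS = ["R", "G", "B", "G_over_Rp1", "B_over_Rp1", "V"]
COLOR_NAMES = [f"color_{stat}_{ch}" for ch in _CHANNELS for stat in ("mean", "std")]


def color_features(crop: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < MIN_MASK_PIXELS:
        raise ValueError(f"mask must cover at least {MIN_MASK_PIXELS} pixels, got {mask.sum()}")
    px = crop[mask].astype(np.float64)  # N x 3
    r, g, b = px[:, 0], px[:, 1], px[:, 2]
    channels = {
        "R": r,
        "G": g,
        "B": b,
        "G_over_Rp1": g / (r + 1.0),
        "B_over_Rp1": b / (r + 1.0),
        "V": px.max(axis=1) / 255.0,
    }
    out: dict[str, float] = {}
    for ch, vals in channels.items():
        out[f"color_mean_{ch}"] = float(vals.mean())
        out[f"color_std_{ch}"] = float(vals.std())
    return out
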