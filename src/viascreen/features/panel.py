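"""Assembly of the 75-feature panel with a fixed name order.

Gray conversion uses the luma weights 0.299 R + 0.587 G + 0.114 B; the
co-occurrence families (GLCM, NGTDM, GLSZM) see an equal-width quantization
of the masked gray range (default 16 levels), while DWT and LBP operate on
the 8-bit gray raster directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from viascreen.features.color import MIN_MASK_PIXELS, COLOR_NAMES, color_features
from viascreen.features.dwt import DWT_NAMES, dwt_features
from viascreen.features.glcm import GLCM_NAMES, glcm_features
from viascreen.features.glszm import GLSZM_NAMES, glszm_features
from viascreen.features.lbp import LBP_NAMES, lbp_features
from viascreen.features.ngtdm import NGTDM_NAMES, ngtdm_features

__all__ = [
    "FEATURE_NAMES",
    "FAMILY_SLICES",
    "to_gray",
    "quantize",
    "extract_all",
    "write_manifest",
]

FEATURE_NAMES: list[str] = (
    COLOR_NAMES + GLCM_NAMES + NGTDM_NAMES + GLSZM_NAMES + DWT_NAMES + LBP_NAMES
)

FAMILY_SLICES: dict[str, slice] = {
    "color": slice(0, 12),
    "glcm": slice(12, 40),
    "ngtdm": slice(40, 45),
    "glszm": slice(45, 59),
    "dwt": slice(59, 65),
    "lbp": slice(65, 75),
}

assert len(FEATURE_NAMES) == 75


def to_gray(crop: np.ndarray) -> np.ndarray:
    """Luma gray conversion of an 8-bit RGB crop (float output, 0..255)."""
    rgb = np.asarray(crop, dtype=np.float64)
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def quantize(gray: np.ndarray, mask: np.ndarray, levels: int = 16) -> np.ndarray:
    """Equal-width quantization of the masked gray range into 0..levels-1.

    A constant region maps to level 0 everywhere.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    g = np.asarray(gray, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    lo, hi = g[mask].min(), g[mask].max()
    if hi - lo < 1e-12:
        return np.zeros_like(g, dtype=np.int64)
    q = np.floor((g - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def extract_all(
    crop: np.ndarray,
    mask: np.ndarray,
    levels: int = 16,
    wavelet: str = "haar",
) -> pd.Series:
    """The full 75-feature vector of one ROI crop, as a named Series."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < MIN_MASK_PIXELS:
        raise ValueError(f"mask must cover at least {MIN_MASK_PIXELS} pixels, got {mask.sum()}")
    gray = to_gray(crop)
    q = quantize(gray, mask, levels)
    values: dict[str, float] = {}
    values.update(color_features(crop, mask))
    values.update(glcm_features(q, mask, levels))
    values.update(ngtdm_features(q, mask, levels))
    values.update(glszm_features(q, mask, levels))
    values.update(dwt_features(gray, mask, wavelet))
    values.update(lbp_features(gray, mask))
    vec = pd.Series([values[name] for name in FEATURE_NAMES], index=FEATURE_NAMES, dtype=float)
    return vec


def write_manifest(path: str | Path) -> None:
    """Ship the column-name manifest (family -> ordered names) as JSON."""
    manifest = {fam: FEATURE_NAMES[sl] for fam, sl in FAMILY_SLICES.items()}
    Path(path).write_text(json.dumps(manifest, indent=2))
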