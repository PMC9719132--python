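"""End-to-end image processing shared by training, evaluation and prediction.

One image travels: resize to the working resolution -> specular-reflection
removal -> GMM cervix ROI -> padded crop zoomed to 200x200 -> 75-feature
panel over the ROI mask. If ROI detection fails (mixture non-convergence or
an empty mask) the pipeline falls back to a whole-image ROI with a warning
rather than refusing a prediction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from viascreen.config import PipelineConfig
from viascreen.errors import EmptyMaskError, RoiConvergenceError
from viascreen.features import extract_all
from viascreen.preprocessing import remove_specular, resize_image
from viascreen.roi import crop_and_zoom, detect_roi

__all__ = ["process_image", "image_features", "build_feature_table"]


def process_image(
    img: np.ndarray, config: PipelineConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Run preprocessing + ROI on one RGB image; return (crop, crop_mask)."""
    config = config or PipelineConfig()
    config.validate()
    resized = resize_image(img, config.resize)
    cleaned = remove_specular(resized, threshold=config.specular_threshold).cleaned
    try:
        roi = detect_roi(cleaned, seed=config.seed, n_components=config.gmm_components)
        return roi.crop, roi.crop_mask
    except (RoiConvergenceError, EmptyMaskError) as exc:
        warnings.warn(f"ROI detection failed ({exc}); falling back to whole-image ROI")
        full = np.ones(cleaned.shape[:2], dtype=bool)
        return crop_and_zoom(cleaned, full)


def image_features(img: np.ndarray, config: PipelineConfig | None = None) -> pd.Series:
    """The 75-feature vector of one image after the full preprocessing chain."""
    config = config or PipelineConfig()
    crop, crop_mask = process_image(img, config)
    if crop_mask.sum() < 64:  # degenerate ROI: extract over the whole crop
        crop_mask = np.ones(crop.shape[:2], dtype=bool)
    return extract_all(crop, crop_mask, levels=config.quantization_levels, wavelet=config.wavelet)


def build_feature_table(
    images: list[np.ndarray],
    ids: list[str],
    labels: list[int] | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Feature table: id, label (NaN when unknown), then the 75 panel columns."""
    config = config or PipelineConfig()
    rows = [image_features(img, config) for img in images]
    table = pd.DataFrame(rows).reset_index(drop=True)
    table.insert(0, "label", labels if labels is not None else np.nan)
    table.insert(0, "id", ids)
    return table
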