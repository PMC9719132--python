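"""Shared fixtures.

The two study-scale fixtures (high-contrast and zero-contrast 199-scene
datasets, split 134/65 with 26/10 positives) are session-scoped because the
full pipeline over 199 images is the expensive part of the suite; every test
that consumes them treats them as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from viascreen.config import PipelineConfig
from viascreen.pipeline import build_feature_table
from viascreen.synthetic import GeneratorConfig, generate_dataset, generate_scene


def split_study(table, n_test_pos=10, n_test_neg=55, seed=0):
    """Class-exact train/test split mirroring the 134/65 study design
    (26 train positives, 10 test positives)."""
    rng = np.random.default_rng(seed)
    pos = table.index[table["label"] == 1].to_numpy()
    neg = table.index[table["label"] == 0].to_numpy()
    rng.shuffle(pos)
    rng.shuffle(neg)
    test_idx = np.concatenate([pos[:n_test_pos], neg[:n_test_neg]])
    train_idx = np.concatenate([pos[n_test_pos:], neg[n_test_neg:]])
    return table.loc[train_idx].reset_index(drop=True), table.loc[test_idx].reset_index(drop=True)


def _features_for(config: GeneratorConfig, n: int, seed: int):
    scenes, _ = generate_dataset(config, n, seed)
    return build_feature_table(
        [s.image for s in scenes],
        ids=[s.scene_id for s in scenes],
        labels=[s.label for s in scenes],
        config=PipelineConfig(seed=seed),
    )


@pytest.fixture(scope="session")
def study_tables():
    """High-contrast 199-scene dataset -> (train 134, test 65) feature tables."""
    table = _features_for(GeneratorConfig(), 199, seed=1)
    return split_study(table, seed=1)


@pytest.fixture(scope="session")
def null_study_tables():
    """Zero-contrast dataset (lesion color equals cervix color) -> train/test."""
    config = GeneratorConfig(lesion_color=GeneratorConfig().cervix_color)
    table = _features_for(config, 199, seed=2)
    return split_study(table, seed=2)


@pytest.fixture(scope="session")
def demo_scene():
    """One positive high-contrast scene with ground truth."""
    return generate_scene(GeneratorConfig(), label=1, seed=3)


@pytest.fixture(scope="session")
def demo_crop_mask(demo_scene):
    """A ROI crop + mask pair from the demo scene, via the real pipeline."""
    from viascreen.pipeline import process_image

    return process_image(demo_scene.image, PipelineConfig())
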