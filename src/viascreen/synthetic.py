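"""Seeded generator of cervix-like scenes with ground-truth masks.

The generator emulates the salient geometry of a post-acetic-acid smartphone
cervix photograph: a roughly circular pink cervix centered in frame, a darker
vaginal-wall surround, small saturated specular highlights, and — for VIA
positive scenes — one matte whitish acetowhite patch with distinct texture
inside the cervix. Every downstream stage (specular removal, ROI detection,
feature extraction, classification) is testable against the planted masks.

Scene k of a dataset draws its random stream from a counter-based child of
the master seed, so it is reproducible independently of batch size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from viascreen.errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "SyntheticScene",
    "generate_scene",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cervix-scene generator.

    Colors are mean RGB triples on the 8-bit scale; each region also carries a
    per-channel Gaussian noise standard deviation. Radii are fractions of the
    reference length noted per field. Defaults reflect the study conditions:
    dataset prevalence 36/199 ≈ 0.181, pink cervix against a darker surround,
    and a clearly whiter, less saturated lesion (high contrast).
    """

    image_size: tuple[int, int] = (400, 400)
    #: cervix disk radius as a fraction of min(H, W)
    cervix_radius_range: tuple[float, float] = (0.28, 0.38)
    cervix_color: tuple[float, float, float] = (195.0, 110.0, 135.0)
    cervix_noise_sd: float = 8.0
    background_color: tuple[float, float, float] = (70.0, 50.0, 55.0)
    background_noise_sd: float = 6.0
    lesion_color: tuple[float, float, float] = (232.0, 214.0, 214.0)
    lesion_noise_sd: float = 8.0
    #: blotch-texture amplitude per unit of lesion/cervix color distance, so a
    #: lesion identical in color to the cervix carries no texture signal either
    lesion_texture_scale: float = 0.2
    n_specular: tuple[int, int] = (3, 8)
    #: specular blob radius in pixels (~1-3% of the frame, as smartphone glints are)
    specular_radius_range: tuple[float, float] = (5.0, 12.0)
    #: lesion semi-axes as fractions of the cervix radius
    lesion_radius_range: tuple[float, float] = (0.25, 0.45)
    prevalence: float = 0.181

    def validate(self) -> None:
        h, w = self.image_size
        if h < 50 or w < 50:
            raise ConfigurationError("image_size: both dimensions must be >= 50")
        for name in ("cervix_radius_range", "specular_radius_range", "lesion_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name}: require 0 < low <= high, got ({lo}, {hi})")
        if self.cervix_radius_range[1] >= 0.5:
            raise ConfigurationError("cervix_radius_range: upper bound must be < 0.5")
        if not (0 <= self.n_specular[0] <= self.n_specular[1]):
            raise ConfigurationError("n_specular: require 0 <= low <= high")
        if self.lesion_radius_range[1] > 0.8:
            raise ConfigurationError("lesion_radius_range: upper bound must be <= 0.8")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError(f"prevalence: must be in [0, 1], got {self.prevalence}")
        for name in ("cervix_color", "background_color", "lesion_color"):
            triple = getattr(self, name)
            if len(triple) != 3 or any(not 0 <= c <= 255 for c in triple):
                raise ConfigurationError(f"{name}: must be an RGB triple in [0, 255]")
        for name in ("cervix_noise_sd", "background_noise_sd", "lesion_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")
        if self.lesion_texture_scale < 0:
            raise ConfigurationError("lesion_texture_scale: must be >= 0")


@dataclass
class SyntheticScene:
    """One generated scene plus its ground truth.

    ``lesion_mask`` is empty when ``label`` is 0; specular pixels are rendered
    with all three channels >= 240 so the specular-removal stage has a
    detectable target.
    """

    image: np.ndarray  # H x W x 3 uint8
    label: int
    cervix_mask: np.ndarray  # H x W bool
    specular_mask: np.ndarray  # H x W bool
    lesion_mask: np.ndarray  # H x W bool
    seed: int
    scene_id: str = field(default="")


def _scene_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def generate_scene(config: GeneratorConfig, label: int, seed: int) -> SyntheticScene:
    """Render one scene. Identical (config, label, seed) gives identical bytes.

    The cervix disk center is jittered by at most 4% of the short image side,
    keeping it within 10% of the frame center. Gaussian pixel noise is applied
    to the matte regions and clipped to [0, 255]; specular highlights are
    painted afterwards so their pixels stay saturated (core values >= 250,
    with a 1-pixel soft rim outside the recorded mask).
    """
    config.validate()
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    rng = _scene_rng(seed)
    h, w = config.image_size
    short = min(h, w)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy = (h - 1) / 2 + rng.uniform(-0.04, 0.04) * short
    cx = (w - 1) / 2 + rng.uniform(-0.04, 0.04) * short
    radius = rng.uniform(*config.cervix_radius_range) * short

    dist = np.hypot(yy - cy, xx - cx)
    cervix_mask = dist <= radius
    # soft 2-px transition so the disk edge is not a single-pixel step
    edge_alpha = np.clip((radius - dist) / 2.0 + 0.5, 0.0, 1.0)

    # compose a noiseless mean field and a blended noise-sd field, then draw a
    # single noise realization: a lesion whose color equals the cervix color is
    # then statistically indistinguishable from surrounding tissue
    mean = np.empty((h, w, 3), dtype=np.float64)
    for c in range(3):
        mean[..., c] = (
            config.background_color[c] * (1 - edge_alpha) + config.cervix_color[c] * edge_alpha
        )
    sd_field = config.background_noise_sd * (1 - edge_alpha) + config.cervix_noise_sd * edge_alpha

    lesion_mask = np.zeros((h, w), dtype=bool)
    if label == 1:
        a_frac = rng.uniform(*config.lesion_radius_range)
        b_frac = rng.uniform(*config.lesion_radius_range)
        a_ax, b_ax = a_frac * radius, b_frac * radius
        theta = rng.uniform(0, np.pi)
        # keep the ellipse strictly inside the cervix disk
        max_off = max(radius - max(a_ax, b_ax) - 3.0, 0.0)
        off_r = rng.uniform(0, max_off)
        off_t = rng.uniform(0, 2 * np.pi)
        ly = cy + off_r * np.sin(off_t)
        lx = cx + off_r * np.cos(off_t)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - lx) * ct + (yy - ly) * st
        v = -(xx - lx) * st + (yy - ly) * ct
        e = np.sqrt((u / a_ax) ** 2 + (v / b_ax) ** 2)  # 1 at the ellipse boundary
        lesion_mask = (e <= 1.0) & cervix_mask
        # Gaussian alpha falloff: matte patch with a soft edge, plus a blotchy
        # low-frequency texture so the lesion differs in texture, not only color;
        # the texture amplitude scales with the lesion/cervix color distance
        alpha = np.exp(-0.5 * (e / 0.55) ** 2)
        color_dist = float(
            np.linalg.norm(np.subtract(config.lesion_color, config.cervix_color))
        )
        amp = config.lesion_texture_scale * color_dist
        texture = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=2.5) * amp
        for c in range(3):
            mean[..., c] = mean[..., c] * (1 - alpha) + (config.lesion_color[c] + texture) * alpha
        sd_field = sd_field * (1 - alpha) + config.lesion_noise_sd * alpha

    img = np.clip(mean + rng.normal(0.0, 1.0, (h, w, 3)) * sd_field[..., None], 0, 255)

    specular_mask = np.zeros((h, w), dtype=bool)
    n_spec = int(rng.integers(config.n_specular[0], config.n_specular[1] + 1))
    for _ in range(n_spec):
        r_spec = rng.uniform(*config.specular_radius_range)
        # highlights concentrate on the (wet, convex) cervix region
        st = rng.uniform(0, 2 * np.pi)
        sr = rng.uniform(0, 0.9 * radius)
        sy, sx = cy + sr * np.sin(st), cx + sr * np.cos(st)
        d = np.hypot(yy - sy, xx - sx)
        core = d <= r_spec
        if not core.any():
            continue
        specular_mask |= core
        rim = (d <= r_spec + 1.0) & ~core
        for c in range(3):
            vals = np.clip(rng.normal(253.0, 1.5, (h, w)), 250.0, 255.0)
            img[..., c] = np.where(core, vals, img[..., c])
            img[..., c] = np.where(rim, 0.5 * img[..., c] + 0.5 * vals, img[..., c])

    return SyntheticScene(
        image=np.clip(img, 0, 255).astype(np.uint8),
        label=int(label),
        cervix_mask=cervix_mask,
        specular_mask=specular_mask,
        lesion_mask=lesion_mask,
        seed=int(seed),
    )


def _child_seed(master_seed: int, index: int) -> int:
    """Counter-based per-scene seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    config: GeneratorConfig, n: int, seed: int
) -> tuple[list[SyntheticScene], pd.DataFrame]:
    """Generate ``n`` scenes with round(n * prevalence) positives.

    Labels are placed by a seeded permutation; scene k's pixels depend only on
    (master seed, k, its label), never on n.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    config.validate()
    n_pos = int(round(n * config.prevalence))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    label_rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(0,)))
    label_rng.shuffle(labels)
    scenes = []
    for k in range(n):
        scene = generate_scene(config, int(labels[k]), _child_seed(seed, k + 1))
        scene.scene_id = f"scene_{k:04d}"
        scenes.append(scene)
    table = pd.DataFrame(
        {
            "id": [s.scene_id for s in scenes],
            "label": [s.label for s in scenes],
            "seed": [s.seed for s in scenes],
        }
    )
    return scenes, table


def save_dataset(scenes: list[SyntheticScene], out_dir: str | Path) -> Path:
    """Write scenes as PNG plus a sidecar JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for s in scenes:
        base = s.scene_id or f"scene_{s.seed}"
        paths = {
            "image": f"{base}.png",
            "cervix_mask": f"{base}_cervix_mask.png",
            "specular_mask": f"{base}_specular_mask.png",
            "lesion_mask": f"{base}_lesion_mask.png",
        }
        Image.fromarray(s.image).save(out / paths["image"])
        for key in ("cervix_mask", "specular_mask", "lesion_mask"):
            mask = getattr(s, key).astype(np.uint8) * 255
            Image.fromarray(mask).save(out / paths[key])
        records.append({"id": base, "label": s.label, "seed": s.seed, "files": paths})
    manifest = out / "dataset.json"
    manifest.write_text(json.dumps(records, indent=2))
    return manifest


def load_dataset(dataset_dir: str | Path) -> list[SyntheticScene]:
    """Read a dataset written by :func:`save_dataset`."""
    root = Path(dataset_dir)
    records = json.loads((root / "dataset.json").read_text())
    scenes = []
    for rec in records:
        files = rec["files"]
        scenes.append(
            SyntheticScene(
                image=np.asarray(Image.open(root / files["image"]).convert("RGB")),
                label=int(rec["label"]),
                cervix_mask=np.asarray(Image.open(root / files["cervix_mask"])) > 127,
                specular_mask=np.asarray(Image.open(root / files["specular_mask"])) > 127,
                lesion_mask=np.asarray(Image.open(root / files["lesion_mask"])) > 127,
                seed=int(rec["seed"]),
                scene_id=rec["id"],
            )
        )
    return scenes
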