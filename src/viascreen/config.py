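"""Pipeline configuration with strict validation.

Defaults pin the published operating point: 200x200 working resolution,
|r| > 0.9 multicollinearity pruning, 25-fold cross-validation optimizing
PrecisionAtRecall(0.8), and a decision threshold of 0.29.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from viascreen.errors import ConfigurationError

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    resize: tuple[int, int] = (200, 200)
    specular_threshold: float = 0.5
    gmm_components: int = 2
    quantization_levels: int = 16
    wavelet: str = "haar"
    collinearity_threshold: float = 0.9
    cv_folds: int = 25
    min_recall: float = 0.8
    decision_threshold: float = 0.29
    seed: int = 0

    def validate(self) -> None:
        h, w = self.resize
        if h < 3 or w < 3:
            raise ConfigurationError("resize: both dimensions must be >= 3")
        if not 0.0 < self.specular_threshold < 1.0:
            raise ConfigurationError("specular_threshold: must be in (0, 1)")
        if self.gmm_components < 2:
            raise ConfigurationError("gmm_components: must be >= 2")
        if self.quantization_levels < 2:
            raise ConfigurationError("quantization_levels: must be >= 2")
        if not 0.0 < self.collinearity_threshold <= 1.0:
            raise ConfigurationError("collinearity_threshold: must be in (0, 1]")
        if self.cv_folds < 2:
            raise ConfigurationError("cv_folds: must be >= 2")
        if not 0.0 < self.min_recall <= 1.0:
            raise ConfigurationError("min_recall: must be in (0, 1]")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigurationError("decision_threshold: must be in (0, 1)")
        if self.seed < 0:
            raise ConfigurationError("seed: must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "resize" in data:
            data["resize"] = tuple(data["resize"])
        cfg = cls(**data)
        cfg.validate()
        return cfg
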