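"""Multicollinearity pruning and z-score normalization.

Fitting happens on training rows only; the fitted state (kept features, drop
provenance, normalization parameters) replays identically at prediction time,
so no test-set information can leak into the transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SelectionState", "fit_selection", "apply_selection"]

_ZERO_VAR_TOL = 1e-12


@dataclass
class SelectionState:
    kept_features: list[str]
    #: dropped feature -> the retained partner that triggered the drop
    #: (the string "zero_variance" when dropped for having no variance)
    dropped_features: dict[str, str]
    zscore_mean: dict[str, float] = field(default_factory=dict)
    zscore_std: dict[str, float] = field(default_factory=dict)
    threshold: float = 0.9

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kept_features": self.kept_features,
                    "dropped_features": self.dropped_features,
                    "zscore_mean": self.zscore_mean,
                    "zscore_std": self.zscore_std,
                    "threshold": self.threshold,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionState":
        return cls(**json.loads(Path(path).read_text()))


def fit_selection(train_table: pd.DataFrame, threshold: float = 0.9) -> SelectionState:
    """Prune features with pairwise |Pearson r| above ``threshold``.

    Zero-variance features are dropped first unconditionally. The remaining
    columns are scanned in panel order over the upper triangle of the absolute
    correlation matrix; when |r(i, j)| > threshold and both are still kept,
    the later column j is dropped, recording i as its retained partner.
    z-score parameters (mean, population std) are then fitted on the kept
    columns.
    """
    if len(train_table) < 3:
        raise ValueError(f"need at least 3 training rows, got {len(train_table)}")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    cols = list(train_table.columns)
    x = train_table.to_numpy(dtype=float)
    stds = x.std(axis=0)
    dropped: dict[str, str] = {c: "zero_variance" for c, s in zip(cols, stds) if s <= _ZERO_VAR_TOL}
    live = [c for c in cols if c not in dropped]
    if live:
        xv = train_table[live].to_numpy(dtype=float)
        corr = np.abs(np.corrcoef(xv, rowvar=False))
        if corr.ndim == 0:  # single surviving column
            corr = np.ones((1, 1))
        keep_flag = {c: True for c in live}
        for i, ci in enumerate(live):
            if not keep_flag[ci]:
                continue
            for j in range(i + 1, len(live)):
                cj = live[j]
                if keep_flag[cj] and corr[i, j] > threshold:
                    keep_flag[cj] = False
                    dropped[cj] = ci
        kept = [c for c in live if keep_flag[c]]
    else:
        kept = []
    if not kept:
        raise ValueError("all features were dropped; lower the threshold or check the data")
    kept_x = train_table[kept].to_numpy(dtype=float)
    return SelectionState(
        kept_features=kept,
        dropped_features=dropped,
        zscore_mean={c: float(m) for c, m in zip(kept, kept_x.mean(axis=0))},
        zscore_std={c: float(s) for c, s in zip(kept, kept_x.std(axis=0))},
        threshold=threshold,
    )


def apply_selection(table: pd.DataFrame, state: SelectionState) -> pd.DataFrame:
    """Project onto the kept features and z-score with the training parameters."""
    missing = [c for c in state.kept_features if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing kept feature columns: {missing}")
    out = table[state.kept_features].astype(float).copy()
    for c in state.kept_features:
        out[c] = (out[c] - state.zscore_mean[c]) / state.zscore_std[c]
    return out
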