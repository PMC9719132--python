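"""Classifier selection, training, thresholded prediction and evaluation.

Nine classical algorithm families compete under 25-fold stratified
cross-validation; the selection metric is PrecisionAtRecall(0.8) — the best
precision attainable at any decision threshold whose recall is at least 0.8,
the natural choice for a screening test that must not miss positives. The
winning family is refit on the full training table and applied with a fixed
decision threshold (default 0.29). Prediction replays the identical
preprocessing, ROI, feature and normalization pipeline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from viascreen.config import PipelineConfig
from viascreen.pipeline import image_features
from viascreen.selection import SelectionState, apply_selection, fit_selection

__all__ = [
    "ALGORITHM_IDS",
    "ConfusionMatrix",
    "CvReport",
    "EvalReport",
    "TrainedModel",
    "make_estimator",
    "precision_at_recall",
    "cross_validate",
    "train_final",
    "predict",
    "compute_metrics",
    "evaluate_scores",
    "evaluate",
]

ALGORITHM_IDS = [
    "gradient_boosting",
    "logistic_regression",
    "random_forest",
    "extra_trees",
    "naive_bayes",
    "adaboost",
    "lightgbm",
    "k_neighbors",
    "decision_tree",
]


def make_estimator(algorithm_id: str, seed: int = 0):
    """Estimator factory with pinned seeds and library-default hyperparameters."""
    if algorithm_id == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if algorithm_id == "logistic_regression":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if algorithm_id == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if algorithm_id == "extra_trees":
        return ExtraTreesClassifier(random_state=seed)
    if algorithm_id == "naive_bayes":
        return GaussianNB()
    if algorithm_id == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    if algorithm_id == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1)
    if algorithm_id == "k_neighbors":
        return KNeighborsClassifier()
    if algorithm_id == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown algorithm id {algorithm_id!r}; valid ids: {ALGORITHM_IDS}")


# ---------------------------------------------------------------- metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def precision_at_recall(
    scores: np.ndarray, labels: np.ndarray, min_recall: float = 0.8
) -> float:
    """Best precision over thresholds t (predict positive iff score >= t)
    subject to recall(t) >= ``min_recall``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not 0.0 < min_recall <= 1.0:
        raise ValueError(f"min_recall must be in (0, 1], got {min_recall}")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("precision_at_recall requires at least one positive label")
    best = 0.0
    feasible = False
    for t in list(np.unique(scores)) + [-np.inf]:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        if tp / n_pos >= min_recall and pred.sum() > 0:
            feasible = True
            best = max(best, tp / int(pred.sum()))
    return best if feasible else 0.0


def compute_metrics(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Sensitivity, specificity, accuracy, precision (3 decimals).

    A ratio whose denominator is zero is reported as None (not applicable),
    never silently as 0.
    """
    out: dict[str, float | None] = {}
    out["sensitivity"] = round(cm.tp / (cm.tp + cm.fn), 3) if cm.tp + cm.fn > 0 else None
    out["specificity"] = round(cm.tn / (cm.tn + cm.fp), 3) if cm.tn + cm.fp > 0 else None
    out["accuracy"] = round((cm.tp + cm.tn) / cm.total, 3) if cm.total > 0 else None
    out["precision"] = round(cm.tp / (cm.tp + cm.fp), 3) if cm.tp + cm.fp > 0 else None
    return out


# ---------------------------------------------------------- cross-validation


@dataclass
class CvReport:
    scores: dict[str, float]  # algorithm id -> mean P@R over folds
    per_fold: dict[str, list[float]]
    ranking: list[tuple[str, float]]  # sorted descending by score
    folds: int
    seed: int

    @property
    def best_algorithm(self) -> str:
        return self.ranking[0][0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scores": self.scores,
                    "per_fold": self.per_fold,
                    "ranking": self.ranking,
                    "folds": self.folds,
                    "seed": self.seed,
                },
                indent=2,
            )
        )


def _split_xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    x = table.drop(columns=[c for c in ("id", "label") if c in table.columns])
    y = table["label"].to_numpy(dtype=int)
    return x, y


def cross_validate(
    train_table: pd.DataFrame,
    algorithms: list[str] | None = None,
    folds: int = 25,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> CvReport:
    """Stratified k-fold selection among the candidate algorithms.

    The pruning + z-score stage is refit inside every training fold; each
    algorithm's fold score is PrecisionAtRecall on the held-out fold.
    """
    config = config or PipelineConfig()
    algorithms = algorithms or ALGORITHM_IDS
    unknown = set(algorithms) - set(ALGORITHM_IDS)
    if unknown:
        raise ValueError(f"unknown algorithm ids {sorted(unknown)}; valid ids: {ALGORITHM_IDS}")
    x, y = _split_xy(train_table)
    n_pos = int(y.sum())
    if n_pos < folds:
        raise ValueError(
            f"only {n_pos} positive rows for {folds} folds; some folds would lack a "
            f"positive and PrecisionAtRecall would be undefined — use fewer folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: dict[str, list[float]] = {a: [] for a in algorithms}
    for train_idx, val_idx in skf.split(x, y):
        state = fit_selection(x.iloc[train_idx], threshold=config.collinearity_threshold)
        x_tr = apply_selection(x.iloc[train_idx], state).to_numpy()
        x_va = apply_selection(x.iloc[val_idx], state).to_numpy()
        y_tr, y_va = y[train_idx], y[val_idx]
        for alg in algorithms:
            est = make_estimator(alg, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(x_tr, y_tr)
                scores = est.predict_proba(x_va)[:, 1]
            per_fold[alg].append(precision_at_recall(scores, y_va, config.min_recall))
    means = {a: float(np.mean(v)) for a, v in per_fold.items()}
    ranking = sorted(means.items(), key=lambda kv: -kv[1])
    return CvReport(scores=means, per_fold=per_fold, ranking=ranking, folds=folds, seed=seed)


# ------------------------------------------------------------- final model


@dataclass
class TrainedModel:
    algorithm_id: str
    estimator: object
    selection_state: SelectionState
    decision_threshold: float
    config: PipelineConfig = field(default_factory=PipelineConfig)

    def save(self, model_dir: str | Path) -> None:
        out = Path(model_dir)
        out.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.estimator, out / "estimator.joblib")
        self.selection_state.to_json(out / "selection.json")
        self.config.to_json(out / "pipeline_config.json")
        (out / "model.json").write_text(
            json.dumps(
                {"algorithm_id": self.algorithm_id, "decision_threshold": self.decision_threshold},
                indent=2,
            )
        )

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedModel":
        root = Path(model_dir)
        meta = json.loads((root / "model.json").read_text())
        return cls(
            algorithm_id=meta["algorithm_id"],
            estimator=joblib.load(root / "estimator.joblib"),
            selection_state=SelectionState.from_json(root / "selection.json"),
            decision_threshold=meta["decision_threshold"],
            config=PipelineConfig.from_json(root / "pipeline_config.json"),
        )


def train_final(
    train_table: pd.DataFrame,
    algorithm_id: str,
    threshold: float = 0.29,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> TrainedModel:
    """Fit selection + estimator on the full training table; store the threshold."""
    config = config or PipelineConfig()
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"decision threshold must be in (0, 1), got {threshold}")
    make_estimator(algorithm_id)  # raises on unknown id before any work
    x, y = _split_xy(train_table)
    state = fit_selection(x, threshold=config.collinearity_threshold)
    est = make_estimator(algorithm_id, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(apply_selection(x, state).to_numpy(), y)
    return TrainedModel(
        algorithm_id=algorithm_id,
        estimator=est,
        selection_state=state,
        decision_threshold=threshold,
        config=config,
    )


def score_table(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Positive-class probability for each row of a feature table."""
    x = table.drop(columns=[c for c in ("id", "label") if c in table.columns])
    return model.estimator.predict_proba(
        apply_selection(x, model.selection_state).to_numpy()
    )[:, 1]


def predict(model: TrainedModel, image: np.ndarray) -> tuple[float, int]:
    """Replay the full pipeline on one image; label = score >= threshold."""
    features = image_features(image, model.config).to_frame().T
    score = float(score_table(model, features)[0])
    return score, int(score >= model.decision_threshold)


# --------------------------------------------------------------- evaluation


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    metrics: dict[str, float | None]
    roc_points: list[tuple[float, float, float]]  # (fpr, tpr, threshold)
    auc: float
    auc_ci: tuple[float, float]
    threshold: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "confusion": vars(self.confusion),
                    "metrics": self.metrics,
                    "auc": self.auc,
                    "auc_ci": list(self.auc_ci),
                    "threshold": self.threshold,
                    "roc_points": self.roc_points,
                },
                indent=2,
            )
        )


def _auc_trapezoid(scores: np.ndarray, labels: np.ndarray) -> float:
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return float(_trapezoid_auc(fpr, tpr))


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    seed: int = 0,
    n_boot: int = 2000,
) -> EvalReport:
    """Confusion at the stored threshold, ROC sweep, trapezoid AUC, and a
    seeded stratified percentile bootstrap 95% CI for the AUC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("evaluation requires at least one positive and one negative label")
    pred = scores >= threshold
    cm = ConfusionMatrix(
        tp=int((pred & (labels == 1)).sum()),
        fp=int((pred & (labels == 0)).sum()),
        tn=int((~pred & (labels == 0)).sum()),
        fn=int((~pred & (labels == 1)).sum()),
    )
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc_value = float(_trapezoid_auc(fpr, tpr))

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
        )
        boot[b] = _auc_trapezoid(scores[idx], labels[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    # the interval always brackets the point estimate
    ci = (float(np.clip(min(lo, auc_value), 0, 1)), float(np.clip(max(hi, auc_value), 0, 1)))
    return EvalReport(
        confusion=cm,
        metrics=compute_metrics(cm),
        roc_points=[(float(f), float(t), float(h)) for f, t, h in zip(fpr, tpr, thr)],
        auc=auc_value,
        auc_ci=ci,
        threshold=threshold,
    )


def evaluate(model: TrainedModel, test_table: pd.DataFrame, seed: int = 0) -> EvalReport:
    """Score a labelled feature table and evaluate at the model's threshold."""
    scores = score_table(model, test_table)
    labels = test_table["label"].to_numpy(dtype=int)
    return evaluate_scores(scores, labels, model.decision_threshold, seed=seed)
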