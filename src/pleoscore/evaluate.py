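"""Classifier-based validation of the features: SVM-RBF cross-validation,
per-class confusion metrics, and the feature-ablation grid.

Scores 1-3 are treated as a three-class problem.  An RBF-kernel SVM is
evaluated with stratified k-fold cross-validation (features standardized
inside each fold, statistics fit on the training folds only).  Metrics
are reported per class one-vs-rest — Accuracy, Recall, Specificity,
Precision, F1 — both from the pooled out-of-fold predictions and as a
mean across folds; "overall" is the unweighted macro average over the
three classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

METRIC_NAMES = ("accuracy", "recall", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and SVM settings.

    Kernel width follows scikit-learn's "scale" rule,
    gamma = 1 / (n_features * Var(X)); regularization C defaults to 1.
    """

    n_folds: int = 5
    c: float = 1.0
    gamma: str | float = "scale"
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class MetricsReport:
    """Cross-validation outcome: per-class and macro metrics."""

    per_class: dict[int, dict[str, float]]
    overall: dict[str, float]
    fold_mean_per_class: dict[int, dict[str, float]]
    fold_mean_overall: dict[str, float]
    confusion: dict[int, ConfusionCounts]
    fold_assignments: np.ndarray
    seed: int
    config: CVConfig = field(repr=False, default=CVConfig())

    def to_dict(self) -> dict:
        return {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "overall": self.overall,
            "fold_mean_per_class": {
                str(k): v for k, v in self.fold_mean_per_class.items()
            },
            "fold_mean_overall": self.fold_mean_overall,
            "confusion": {
                str(k): {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn}
                for k, c in self.confusion.items()
            },
            "seed": self.seed,
            "n_folds": self.config.n_folds,
        }


def per_class_confusion(predicted, truth, positive_class) -> ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN for one class."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    pos_pred = predicted == positive_class
    pos_true = truth == positive_class
    return ConfusionCounts(
        tp=int((pos_pred & pos_true).sum()),
        tn=int((~pos_pred & ~pos_true).sum()),
        fp=int((pos_pred & ~pos_true).sum()),
        fn=int((~pos_pred & pos_true).sum()),
    )


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, Recall, Specificity, Precision, F1 from confusion counts.

    Undefined ratios (0/0) are reported as 0.0 and flagged under
    ``undefined``.
    """
    if c.total == 0:
        raise ValueError("empty confusion counts")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    recall = ratio(c.tp, c.tp + c.fn, "recall")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    out = {
        "accuracy": (c.tp + c.tn) / c.total,
        "recall": recall,
        "specificity": ratio(c.tn, c.tn + c.fp, "specificity"),
        "precision": precision,
        "f1": (
            2 * recall * precision / (recall + precision)
            if (recall + precision) > 0
            else (undefined.append("f1") or 0.0)
        ),
    }
    out["undefined"] = undefined
    return out


def _macro(per_class: dict[int, dict[str, float]]) -> dict[str, float]:
    return {
        m: float(np.mean([per_class[k][m] for k in per_class]))
        for m in METRIC_NAMES
    }


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float)
    x = np.asarray(features, dtype=float)
    return x.reshape(-1, 1) if x.ndim == 1 else x


def cross_validate_svm(features, labels, cfg: CVConfig = CVConfig()) -> MetricsReport:
    """Stratified k-fold SVM-RBF evaluation.

    Pooled out-of-fold predictions produce per-class confusion counts and
    metrics; per-fold metrics averaged across folds are reported
    alongside.  Deterministic for a fixed seed.
    """
    x = _as_matrix(features)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have equal length")
    classes = np.unique(y)
    counts = {int(k): int((y == k).sum()) for k in classes}
    if cfg.stratified and min(counts.values()) < cfg.n_folds:
        raise ValueError(
            f"each class needs >= {cfg.n_folds} samples for stratified folds; got {counts}"
        )
    splitter = StratifiedKFold(
        n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
    )
    predictions = np.empty_like(y)
    fold_assignments = np.empty(y.shape[0], dtype=int)
    fold_metrics: list[dict[int, dict[str, float]]] = []
    for fold, (train, test) in enumerate(splitter.split(x, y)):
        model = make_pipeline(
            StandardScaler(), SVC(kernel="rbf", C=cfg.c, gamma=cfg.gamma)
        )
        model.fit(x[train], y[train])
        pred = model.predict(x[test])
        predictions[test] = pred
        fold_assignments[test] = fold
        fold_metrics.append(
            {
                int(k): metrics(per_class_confusion(pred, y[test], k))
                for k in classes
            }
        )

    confusion = {int(k): per_class_confusion(predictions, y, k) for k in classes}
    per_class = {k: metrics(c) for k, c in confusion.items()}
    fold_mean_per_class = {
        int(k): {
            m: float(np.mean([fm[int(k)][m] for fm in fold_metrics]))
            for m in METRIC_NAMES
        }
        for k in classes
    }
    return MetricsReport(
        per_class=per_class,
        overall=_macro(per_class),
        fold_mean_per_class=fold_mean_per_class,
        fold_mean_overall=_macro(fold_mean_per_class),
        confusion=confusion,
        fold_assignments=fold_assignments,
        seed=cfg.seed,
        config=cfg,
    )


def ablation(
    feature_table: pd.DataFrame,
    labels,
    subsets: dict[str, list[str]],
    cfg: CVConfig = CVConfig(),
) -> pd.DataFrame:
    """Feature-ablation grid: one cross-validation per feature subset.

    Returns a table with one row per subset and columns
    ``f1_score_<class>`` per class plus macro ``f1_overall``, with the
    classifier configuration held fixed across rows.
    """
    if not subsets:
        raise ValueError("at least one feature subset is required")
    rows = []
    for name, cols in subsets.items():
        if not cols:
            raise ValueError(f"subset {name!r} is empty")
        missing = [c for c in cols if c not in feature_table.columns]
        if missing:
            raise KeyError(f"unknown feature column(s) {missing} in subset {name!r}")
        report = cross_validate_svm(feature_table[list(cols)], labels, cfg)
        row = {"features": name}
        for k in sorted(report.per_class):
            row[f"f1_score_{k}"] = report.per_class[k]["f1"]
        row["f1_overall"] = report.overall["f1"]
        rows.append(row)
    return pd.DataFrame(rows)


#: The standard ablation grid: each element alone, each pair, and HM.
DEFAULT_ABLATION_SUBSETS: dict[str, list[str]] = {
    "e_size": ["e_size"],
    "e_shape": ["e_shape"],
    "e_appearance": ["e_appearance"],
    "e_size+e_shape": ["e_size", "e_shape"],
    "e_size+e_appearance": ["e_size", "e_appearance"],
    "e_shape+e_appearance": ["e_shape", "e_appearance"],
    "hm": ["hm"],
}
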