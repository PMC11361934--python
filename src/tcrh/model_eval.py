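"""Binary classifiers and the evaluation metric suite.

The primary model is an RBF-kernel SVM with the standard defaults
(C = 1, gamma = 1 / (n_features * Var(X)), the "scale" heuristic); random
forest, gradient boosting and extreme gradient boosting are available as
comparators. Confusion counts, the five threshold metrics and the
rank-statistic ROC AUC are computed here from first principles so that every
reported number is recomputable from the stored counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.svm import SVC

ALGORITHMS = ("svm_rbf", "random_forest", "gradient_boosting",
              "extreme_gradient_boosting")

#: library defaults pinned explicitly so "default hyperparameters" stays
#: reproducible across library versions; echoed into the run log.
DEFAULT_HYPERPARAMETERS = {
    "svm_rbf": {"C": 1.0, "kernel": "rbf", "gamma": "scale"},
    "random_forest": {"n_estimators": 100, "criterion": "gini",
                      "max_depth": None, "max_features": "sqrt"},
    "gradient_boosting": {"n_estimators": 100, "learning_rate": 0.1,
                          "max_depth": 3, "subsample": 1.0},
    "extreme_gradient_boosting": {"n_estimators": 100, "learning_rate": 0.3,
                                  "max_depth": 6, "reg_lambda": 1.0},
}


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str = "svm_rbf"
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def resolved_hyperparameters(self) -> dict:
        return {**DEFAULT_HYPERPARAMETERS[self.algorithm], **self.hyperparameters}


@dataclass
class TrainedModel:
    """A fitted classifier plus its feature-name contract.

    ``decision_scores`` are oriented so that larger means more likely binder;
    SVMs score with the decision function (natural threshold 0), the
    probability-emitting comparators with P(class 1) (natural threshold 0.5).
    """

    estimator: object
    feature_names: tuple
    spec: ModelSpec
    default_threshold: float

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if tuple(X.columns) != self.feature_names:
            raise ValueError("feature names/order differ from training")
        return X.to_numpy()


def train_classifier(spec: ModelSpec, X: pd.DataFrame, y) -> TrainedModel:
    """Fit the requested classifier on a scaled, pruned feature matrix."""
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("y must contain both classes 0 and 1")
    hp = spec.resolved_hyperparameters()
    if spec.algorithm == "svm_rbf":
        est = SVC(**hp)  # deterministic given data; no RNG in the dual solve
        thr = 0.0
    elif spec.algorithm == "random_forest":
        est = RandomForestClassifier(**hp, random_state=spec.seed)
        thr = 0.5
    elif spec.algorithm == "gradient_boosting":
        est = GradientBoostingClassifier(**hp, random_state=spec.seed)
        thr = 0.5
    else:
        from xgboost import XGBClassifier
        est = XGBClassifier(**hp, random_state=spec.seed)
        thr = 0.5
    est.fit(X.to_numpy(), y)
    return TrainedModel(est, tuple(X.columns), spec, thr)


def decision_scores(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Real-valued scores, larger = more likely binder."""
    arr = model._check(X)
    if isinstance(model.estimator, SVC):
        return model.estimator.decision_function(arr)
    return model.estimator.predict_proba(arr)[:, 1]


def predict_labels(model: TrainedModel, X: pd.DataFrame,
                   threshold: float | None = None) -> np.ndarray:
    """Binary labels from scores: 1 iff score > threshold."""
    thr = model.default_threshold if threshold is None else threshold
    return (decision_scores(model, X) > thr).astype(int)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def confusion(y_true, y_pred) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) with positives = label 1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    for arr in (y_true, y_pred):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def metrics(tp: int, tn: int, fp: int, fn: int) -> dict:
    """Accuracy, precision, recall, specificity and F1 from confusion counts.

    A 0/0 denominator yields NaN and the metric's name in the ``undefined``
    list — never a silent zero.
    """
    counts = dict(tp=tp, tn=tn, fp=fp, fn=fn)
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    if sum(counts.values()) == 0:
        raise ValueError("all counts zero")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    out = {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "precision": precision,
        "recall": recall,
        "specificity": ratio(tn, tn + fp, "specificity"),
        "f1": (ratio(2 * precision * recall, precision + recall, "f1")
               if precision == precision and recall == recall else float("nan")),
        "undefined": undefined,
    }
    if out["f1"] != out["f1"] and "f1" not in undefined and (
            "precision" in undefined or "recall" in undefined):
        undefined.append("f1")
    return out


def roc_auc(scores, y_true) -> float:
    """Rank-statistic AUC: P(random positive outscores random negative),
    ties counted 1/2; equal to the trapezoidal area under the ROC curve."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    pos_rank_sum = float(ranks[y_true == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_points(scores, y_true) -> list[tuple[float, float]]:
    """(FPR, TPR) at every score threshold, from (0,0) to (1,1)."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    n_pos = max(int((y_true == 1).sum()), 1)
    n_neg = max(int((y_true == 0).sum()), 1)
    pts = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(y_sorted)):
        if y_sorted[i] == 1:
            tp += 1
        else:
            fp += 1
        last_of_tie = i + 1 == len(y_sorted) or s_sorted[i + 1] != s_sorted[i]
        if last_of_tie:
            pts.append((fp / n_neg, tp / n_pos))
    return pts


@dataclass(frozen=True)
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc_roc: float
    roc: list = field(default_factory=list, repr=False)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "tn", "fp", "fn", "accuracy", "precision", "recall",
                 "specificity", "f1", "auc_roc")}


def evaluate(model: TrainedModel, X: pd.DataFrame, y,
             threshold: float | None = None) -> EvalReport:
    """Score a test matrix and assemble the full metric report."""
    scores = decision_scores(model, X)
    thr = model.default_threshold if threshold is None else threshold
    y_pred = (scores > thr).astype(int)
    tp, tn, fp, fn = confusion(y, y_pred)
    m = metrics(tp, tn, fp, fn)
    return EvalReport(tp, tn, fp, fn, m["accuracy"], m["precision"], m["recall"],
                      m["specificity"], m["f1"], roc_auc(scores, y),
                      roc_points(scores, y))
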