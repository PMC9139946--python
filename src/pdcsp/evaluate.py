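"""Classifier training, k-fold cross-validation, and performance metrics.

The full evaluation chain, per fold: fit the CSP projection on the training
segments only, spatially filter and featurise both partitions with that
fold's projection, train the classifier on the training features, and score
the held-out fold.  Fold metrics (accuracy, sensitivity, specificity,
precision, F-score, all on the percent scale, plus trapezoidal ROC/AUC) are
reported per fold and as mean +/- standard deviation across folds.

"Positive" is the patient class (class A of the CSP fit), so sensitivity
measures patient detection and specificity control detection.

Cross-validation is segment-level by default, matching the common practice
of treating every segment as an independent sample; because segments from
one subject are correlated, an optional subject-blocked mode
(``cv_mode="subject"``) keeps each subject's segments in a single fold for
a more conservative generalisation estimate.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .csp import CSPModel, fit_csp
from .features import FeatureConfig, extract_features
from .preprocess import BandSpec, SegmentSet, preprocess

__all__ = [
    "ClassifierSpec",
    "ConfusionCounts",
    "FoldResult",
    "EvalResult",
    "make_classifier",
    "positive_scores",
    "kfold_indices",
    "train_classifier",
    "confusion_metrics",
    "roc_auc",
    "evaluate_segments",
    "run_pipeline",
    "CLASSIFIER_KINDS",
]

CLASSIFIER_KINDS = ("RF", "LDA", "QDA", "SVM", "KNN")

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f_score")


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to train and its (few) hyperparameters.

    The SVM kernel is fixed to an inhomogeneous quadratic polynomial;
    KNN uses Euclidean distance with an odd neighbour count to avoid vote
    ties in the binary problem.
    """

    kind: str = "KNN"
    knn_k: int = 3
    rf_trees: int = 100
    svm_c: float = 1.0
    qda_reg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier {self.kind!r}; choose from {CLASSIFIER_KINDS}")
        if self.kind == "KNN" and self.knn_k % 2 == 0:
            raise ValueError(f"knn_k must be odd to avoid vote ties, got {self.knn_k}")


def make_classifier(spec: ClassifierSpec):
    """Instantiate the sklearn estimator for a spec (unfitted)."""
    if spec.kind == "RF":
        return RandomForestClassifier(n_estimators=spec.rf_trees, random_state=spec.seed)
    if spec.kind == "LDA":
        return LinearDiscriminantAnalysis()
    if spec.kind == "QDA":
        return QuadraticDiscriminantAnalysis(reg_param=spec.qda_reg)
    if spec.kind == "SVM":
        return SVC(kernel="poly", degree=2, coef0=1.0, C=spec.svm_c)
    if spec.kind == "KNN":
        return KNeighborsClassifier(n_neighbors=spec.knn_k, metric="euclidean")
    raise AssertionError(spec.kind)


def train_classifier(spec: ClassifierSpec, features: np.ndarray, labels: Sequence):
    """Fit the classifier; returns the fitted sklearn estimator."""
    clf = make_classifier(spec)
    clf.fit(np.asarray(features, dtype=float), np.asarray(labels))
    return clf


def positive_scores(clf, features: np.ndarray, positive) -> np.ndarray:
    """Continuous score per sample, larger = more like the positive class.

    Probability-based for KNN/RF/LDA/QDA (neighbour-vote fraction,
    tree-vote fraction, posterior); signed margin for the SVM.
    """
    features = np.asarray(features, dtype=float)
    classes = list(clf.classes_)
    idx = classes.index(positive)
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(features)[:, idx]
    margin = clf.decision_function(features)
    # sklearn's margin is positive towards classes_[1]
    return margin if idx == 1 else -margin


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "TN", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            TP=int(np.sum(pos_t & pos_p)),
            FP=int(np.sum(~pos_t & pos_p)),
            TN=int(np.sum(~pos_t & ~pos_p)),
            FN=int(np.sum(pos_t & ~pos_p)),
        )


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy/sensitivity/specificity/precision/F-score in percent.

    Metrics with a zero denominator are reported as NaN and listed under
    the ``"undefined"`` key rather than silently coerced to 0.
    """
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    undefined: list[str] = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return 100.0 * num / den

    accuracy = ratio(tp + tn, counts.total, "accuracy")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        undefined.append("f_score")
        f_score = math.nan
    else:
        f_score = 2.0 * precision * sensitivity / (precision + sensitivity)
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "f_score": f_score,
        "undefined": undefined,
    }


def roc_auc(scores: Sequence[float], labels: Sequence, positive) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a score-threshold sweep plus trapezoid AUC."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    y = (labels == positive).astype(int)
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def kfold_indices(M: int, k: int, labels: Sequence, seed: int = 0,
                  groups: Sequence | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition of ``range(M)``; reproducible for a seed.

    With ``groups`` (subject ids) the partition is additionally
    group-blocked so no subject straddles folds.  A class with fewer than
    ``k`` members triggers a warning and an unstratified best-effort split.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if M < k:
        raise ValueError(f"cannot make {k} folds from {M} samples")
    labels = np.asarray(labels)
    if len(labels) != M:
        raise ValueError("labels length must equal M")
    X_dummy = np.zeros((M, 1))
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(X_dummy, labels, groups=np.asarray(groups))]
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} < k={k} members; "
            "falling back to unstratified folds", stacklevel=2)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(X_dummy)]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(X_dummy, labels)]


@dataclass
class FoldResult:
    counts: ConfusionCounts
    metrics: dict
    auc: float
    roc_points: np.ndarray
    csp_model: CSPModel | None = None  # kept for leakage audits; not serialised


@dataclass
class EvalResult:
    """Per-fold results plus mean/std aggregates of every metric."""

    per_fold: list[FoldResult]
    positive: str
    config: dict = field(default_factory=dict)

    def _values(self, name: str) -> np.ndarray:
        if name == "auc":
            return np.array([f.auc for f in self.per_fold])
        return np.array([f.metrics[name] for f in self.per_fold])

    def mean(self, name: str) -> float:
        return float(np.nanmean(self._values(name)))

    def std(self, name: str) -> float:
        return float(np.nanstd(self._values(name)))

    def summary(self) -> dict:
        return {name: {"mean": self.mean(name), "std": self.std(name)}
                for name in (*METRIC_NAMES, "auc")}

    def to_dict(self) -> dict:
        return {
            "positive": self.positive,
            "config": self.config,
            "summary": self.summary(),
            "folds": [
                {
                    "counts": {"TP": f.counts.TP, "FP": f.counts.FP,
                               "TN": f.counts.TN, "FN": f.counts.FN},
                    "metrics": {k: v for k, v in f.metrics.items() if k != "undefined"},
                    "undefined": f.metrics["undefined"],
                    "auc": f.auc,
                }
                for f in self.per_fold
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def roc_to_csv(self, path: str | Path) -> None:
        frames = []
        for i, f in enumerate(self.per_fold):
            df = pd.DataFrame(f.roc_points, columns=["fpr", "tpr"])
            df.insert(0, "fold", i)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def evaluate_segments(
    segment_set: SegmentSet,
    m: int | None = None,
    feature_config: FeatureConfig | None = None,
    classifier_spec: ClassifierSpec | None = None,
    k: int = 10,
    seed: int = 0,
    cv_mode: str = "segment",
    positive: str | None = None,
) -> EvalResult:
    """Cross-validated evaluation of a segment set.

    The CSP projection and the classifier are fit on each fold's training
    segments only and reused, frozen, on that fold's test segments.
    """
    feature_config = feature_config or FeatureConfig()
    classifier_spec = classifier_spec or ClassifierSpec(seed=seed)
    labels = segment_set.labels
    uniq = sorted(np.unique(labels).tolist())
    if len(uniq) != 2:
        raise ValueError(f"evaluation is two-class; got {uniq}")
    if positive is None:
        positive = next((g for g in ("PD_OFF", "PD_ON") if g in uniq), uniq[0])
    negative = next(u for u in uniq if u != positive)
    if cv_mode not in ("segment", "subject"):
        raise ValueError("cv_mode must be 'segment' or 'subject'")
    groups = segment_set.subject_ids if cv_mode == "subject" else None
    folds = kfold_indices(segment_set.M, k, labels, seed=seed, groups=groups)

    per_fold = []
    for fold_i, (train_idx, test_idx) in enumerate(folds):
        try:
            model = fit_csp(segment_set.segments[train_idx], labels[train_idx],
                            positive, negative, m=m)
            train_view = SegmentSet(segment_set.segments[train_idx], labels[train_idx],
                                    T=segment_set.T, fs=segment_set.fs)
            test_view = SegmentSet(segment_set.segments[test_idx], labels[test_idx],
                                   T=segment_set.T, fs=segment_set.fs)
            train_feat = extract_features(model, train_view, feature_config)
            test_feat = extract_features(model, test_view, feature_config)
            clf = train_classifier(classifier_spec, train_feat.values, train_feat.labels)
            y_pred = clf.predict(test_feat.values)
            scores = positive_scores(clf, test_feat.values, positive)
            counts = ConfusionCounts.from_predictions(test_feat.labels, y_pred, positive)
            roc_points, auc = roc_auc(scores, test_feat.labels, positive)
        except Exception as exc:
            raise RuntimeError(f"fold {fold_i}: {exc}") from exc
        per_fold.append(FoldResult(counts=counts, metrics=confusion_metrics(counts),
                                   auc=auc, roc_points=roc_points, csp_model=model))
    config = {
        "m": m, "k": k, "seed": seed, "cv_mode": cv_mode,
        "metric": feature_config.metric, "classifier": classifier_spec.kind,
    }
    return EvalResult(per_fold=per_fold, positive=positive, config=config)


def run_pipeline(
    recordings,
    band: BandSpec | None = None,
    T: float = 2.0,
    m: int | None = None,
    feature_config: FeatureConfig | None = None,
    classifier_spec: ClassifierSpec | None = None,
    k: int = 10,
    seed: int = 0,
    cv_mode: str = "segment",
    positive: str | None = None,
) -> EvalResult:
    """Band-pass, segment, and cross-validate a list of recordings."""
    band = band or BandSpec()
    segment_set = preprocess(recordings, band, T)
    result = evaluate_segments(segment_set, m=m, feature_config=feature_config,
                               classifier_spec=classifier_spec, k=k, seed=seed,
                               cv_mode=cv_mode, positive=positive)
    result.config.update({"band": [band.low_hz, band.high_hz], "T": T})
    return result
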