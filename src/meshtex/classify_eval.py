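"""Classifier adapters, GWO-tuned training, and the evaluation protocol.

The five classifiers (random forest, gradient boosting, k-nearest
neighbours, multilayer perceptron, support vector classifier) are thin
adapters over scikit-learn — the bespoke surface here is the search space
each one exposes to the Grey Wolf optimiser, the leakage-safe stratified
protocol (80:20 held-out test, stratified k-fold tuning on the training
split only, augmented variants kept on the same side of every boundary as
their originals), and the report: per-class precision/recall, overall
accuracy in percent, confusion counts and one-vs-rest ROC curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .imaging_io import LabeledSet
from .optimizer import Dimension, GWOConfig, OptResult, SearchSpace, optimize

__all__ = [
    "ClassifierSpec", "SplitPlan", "EvalReport",
    "stratified_split", "precision", "recall", "accuracy", "roc_points",
    "train_with_gwo", "evaluate", "make_classifier", "CLASSIFIER_SPECS",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier name, its estimator factory inputs, and its GWO space."""

    name: str
    search_space: SearchSpace
    defaults: dict[str, Any]


def _spaces() -> dict[str, ClassifierSpec]:
    return {
        "rf": ClassifierSpec(
            "rf",
            SearchSpace((
                Dimension("n_estimators", "integer", 20, 150),
                Dimension("max_depth", "integer", 2, 20),
                Dimension("min_samples_split", "integer", 2, 10),
            )),
            {"n_estimators": 100, "max_depth": 10, "min_samples_split": 2},
        ),
        "gb": ClassifierSpec(
            "gb",
            SearchSpace((
                Dimension("learning_rate", "continuous", 0.01, 0.5),
                Dimension("n_estimators", "integer", 20, 150),
                Dimension("max_depth", "integer", 1, 6),
            )),
            {"learning_rate": 0.1, "n_estimators": 100, "max_depth": 3},
        ),
        "knn": ClassifierSpec(
            "knn",
            SearchSpace((
                Dimension("n_neighbors", "integer", 1, 15),
                Dimension("metric", "categorical",
                          categories=("euclidean", "manhattan")),
            )),
            {"n_neighbors": 5, "metric": "euclidean"},
        ),
        "ann": ClassifierSpec(
            "ann",
            SearchSpace((
                Dimension("neurons", "integer", 4, 64),
                Dimension("learning_rate_init", "continuous", 1e-4, 0.1),
                Dimension("batch_size", "integer", 8, 64),
            )),
            {"neurons": 32, "learning_rate_init": 1e-3, "batch_size": 16},
        ),
        "svc": ClassifierSpec(
            "svc",
            SearchSpace((
                Dimension("C", "continuous", 0.1, 100.0),
                Dimension("kernel", "categorical",
                          categories=("linear", "rbf", "poly")),
            )),
            {"C": 1.0, "kernel": "rbf"},
        ),
    }


CLASSIFIER_SPECS: dict[str, ClassifierSpec] = _spaces()

#: Hidden-layer depth of the MLP adapter (tunable width per layer).
ANN_DEPTH = 10


def make_classifier(name: str, params: dict[str, Any] | None = None,
                    seed: int = 0, ann_depth: int = ANN_DEPTH,
                    l1: bool = False):
    """Instantiate the scikit-learn estimator behind an adapter name."""
    if name not in CLASSIFIER_SPECS:
        raise ValueError(f"unknown classifier {name!r}; "
                         f"choose from {sorted(CLASSIFIER_SPECS)}")
    p = dict(CLASSIFIER_SPECS[name].defaults)
    p.update(params or {})
    if name == "rf":
        return RandomForestClassifier(random_state=seed, **p)
    if name == "gb":
        return GradientBoostingClassifier(random_state=seed, **p)
    if name == "knn":
        return KNeighborsClassifier(**p)
    if name == "ann":
        hidden = (int(p["neurons"]),) * ann_depth
        return MLPClassifier(
            hidden_layer_sizes=hidden,
            learning_rate_init=p["learning_rate_init"],
            batch_size=int(p["batch_size"]),
            max_iter=300, random_state=seed,
            alpha=1e-2 if l1 else 1e-4,
        )
    return SVC(C=p["C"], kernel=p["kernel"], probability=True, random_state=seed)


@dataclass(frozen=True)
class SplitPlan:
    """Held-out fraction, tuning fold count, and the seed that fixes both."""

    test_fraction: float = 0.2
    k_folds: int = 5
    seed: int = 0
    stratified: bool = True


@dataclass
class EvalReport:
    """Per-class and overall evaluation results from a fitted model."""

    class_names: list[str]
    confusion: np.ndarray                      # rows true, cols predicted
    precision_per_class: dict[str, float]
    recall_per_class: dict[str, float]
    accuracy_pct: float
    counts: dict[str, dict[str, int]]          # per class: TP/FP/FN/TN
    roc: dict[str, tuple[np.ndarray, np.ndarray]]  # class -> (FPR, TPR)

    def as_dict(self) -> dict[str, Any]:
        return {
            "class_names": self.class_names,
            "confusion": self.confusion.tolist(),
            "precision": self.precision_per_class,
            "recall": self.recall_per_class,
            "accuracy_pct": self.accuracy_pct,
            "counts": self.counts,
            "roc": {c: [f.tolist(), t.tolist()] for c, (f, t) in self.roc.items()},
        }


def stratified_split(dataset: LabeledSet, plan: SplitPlan = SplitPlan()
                     ) -> tuple[LabeledSet, LabeledSet]:
    """80:20 (by default) stratified train/test partition of a labeled set.

    Only original images are partitioned here; augmentation, if used, is
    applied afterwards to the training side so variants can never leak into
    the test set.
    """
    labels = np.asarray(dataset.labels)
    for cls, cnt in zip(*np.unique(labels, return_counts=True)):
        if cnt < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
    idx = np.arange(len(dataset))
    tr, te = train_test_split(
        idx, test_size=plan.test_fraction, random_state=plan.seed,
        stratify=labels if plan.stratified else None,
    )
    def subset(ix: np.ndarray) -> LabeledSet:
        return LabeledSet(
            images=[dataset.images[i] for i in ix],
            labels=[dataset.labels[i] for i in ix],
            class_names=list(dataset.class_names),
            origins=[dataset.origins[i] for i in ix],
        )
    return subset(np.sort(tr)), subset(np.sort(te))


def precision(tp: int, fp: int) -> float:
    """TP / (TP + FP); 0 (with a warning) when no positive predictions exist."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        warnings.warn("precision undefined (no predicted positives); returning 0")
        return 0.0
    return tp / (tp + fp)


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); 0 (with a warning) when no actual positives exist."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        warnings.warn("recall undefined (no actual positives); returning 0")
        return 0.0
    return tp / (tp + fn)


def accuracy(n_correct: int, n_total: int) -> float:
    """Overall accuracy as a percentage: 100 * correct / total."""
    if n_total < 1:
        raise ValueError("total count must be >= 1")
    if not 0 <= n_correct <= n_total:
        raise ValueError("correct count must lie in [0, total]")
    return 100.0 * n_correct / n_total


def roc_points(scores: np.ndarray, labels: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """ROC staircase (FPR, TPR) swept over all score thresholds.

    Requires both classes present; the curve runs from (0, 0) to (1, 1)
    with both coordinates non-decreasing.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs at least one positive and one negative label")
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    if fpr[0] != 0 or tpr[0] != 0:
        fpr = np.concatenate([[0.0], fpr])
        tpr = np.concatenate([[0.0], tpr])
    return fpr, tpr


def _fold_indices(y: np.ndarray, origins: np.ndarray, variant: np.ndarray,
                  plan: SplitPlan) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds over originals; each fold's train side also gets the
    augmented variants whose source original is in that train side."""
    orig_idx = np.flatnonzero(~variant)
    skf = StratifiedKFold(n_splits=plan.k_folds, shuffle=True,
                          random_state=plan.seed)
    folds = []
    for tr, va in skf.split(orig_idx, y[orig_idx]):
        tr_orig = orig_idx[tr]
        va_orig = orig_idx[va]
        tr_origins = set(origins[tr_orig])
        extra = np.flatnonzero(variant & np.isin(origins, list(tr_origins)))
        folds.append((np.concatenate([tr_orig, extra]), va_orig))
    return folds


def train_with_gwo(X: np.ndarray, y: np.ndarray, name: str = "rf",
                   plan: SplitPlan = SplitPlan(),
                   gwo: GWOConfig = GWOConfig(),
                   origins: np.ndarray | None = None,
                   variant_mask: np.ndarray | None = None,
                   ) -> tuple[Any, OptResult]:
    """GWO-tune a classifier on the training split and refit with the winner.

    Fitness is the mean stratified k-fold validation accuracy over the
    training data only.  Validation folds contain only original samples;
    augmented variants train with — and only with — their source fold.  The
    default hyperparameters are seeded into the initial pack, so the tuned
    fitness can never fall below the default-configuration fitness.
    """
    if name not in CLASSIFIER_SPECS:
        raise ValueError(f"unknown classifier {name!r}")
    spec = CLASSIFIER_SPECS[name]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    origins = np.arange(n) if origins is None else np.asarray(origins)
    variant = (np.zeros(n, dtype=bool) if variant_mask is None
               else np.asarray(variant_mask, dtype=bool))
    counts = np.unique(y[~variant], return_counts=True)[1]
    if counts.min() < plan.k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} originals; "
            f"cannot form {plan.k_folds} stratified folds")

    folds = _fold_indices(y, origins, variant, plan)

    def fitness(params: dict[str, Any]) -> float:
        accs = []
        for tr, va in folds:
            model = make_classifier(name, params, seed=plan.seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            accs.append(float(np.mean(model.predict(X[va]) == y[va])))
        return float(np.mean(accs))

    default_pos = _encode_defaults(spec)
    result = optimize(fitness, spec.search_space, gwo,
                      initial_positions=[default_pos])
    final = make_classifier(name, result.best_params, seed=plan.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return final, result


def _encode_defaults(spec: ClassifierSpec) -> np.ndarray:
    pos = []
    for dim in spec.search_space.dimensions:
        v = spec.defaults[dim.name]
        if dim.kind == "categorical":
            pos.append(float(dim.categories.index(v)))
        else:
            pos.append(float(v))
    return np.array(pos)


def evaluate(model, X: np.ndarray, y: np.ndarray,
             class_names: list[str] | None = None) -> EvalReport:
    """Confusion counts, per-class precision/recall, accuracy %, and ROC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(y) == 0:
        raise ValueError("test set is empty")
    if X.shape[1] != getattr(model, "n_features_in_", X.shape[1]):
        raise ValueError(
            f"feature length {X.shape[1]} does not match the "
            f"{model.n_features_in_} features the model was trained on")
    pred = model.predict(X)
    classes = class_names or sorted(set(map(str, np.unique(y))))
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k), dtype=int)
    for t, p in zip(y, pred):
        conf[index[str(t)], index[str(p)]] += 1

    counts, precs, recs = {}, {}, {}
    for c in classes:
        i = index[c]
        tp = int(conf[i, i])
        fp = int(conf[:, i].sum() - tp)
        fn = int(conf[i, :].sum() - tp)
        tn = int(conf.sum() - tp - fp - fn)
        counts[c] = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            precs[c] = precision(tp, fp)
            recs[c] = recall(tp, fn)

    acc = accuracy(int(np.trace(conf)), int(conf.sum()))

    roc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        model_classes = [str(c) for c in model.classes_]
        for c in classes:
            binary = (np.asarray([str(v) for v in y]) == c).astype(int)
            if c in model_classes and 0 < binary.sum() < len(binary):
                roc[c] = roc_points(proba[:, model_classes.index(c)], binary)

    return EvalReport(class_names=list(classes), confusion=conf,
                      precision_per_class=precs, recall_per_class=recs,
                      accuracy_pct=acc, counts=counts, roc=roc)
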