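"""Multiclass TE type prediction (DATE / TIME / DURATION / SET).

The default algorithm mirrors the best-performing configuration for this
task: a randomizable filtered classifier, i.e. a seeded Gaussian random
projection of the sparse feature vectors followed by 1-nearest-neighbor
classification in the projected space.  Plain KNN, logistic regression and a
decision-stump boosting ensemble are available through the same registry for
comparison.  Everything is bit-reproducible given (data, config, seed).
"""

from __future__ import annotations

import pickle
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .eval_suite import EvalReport, macro_metrics
from .timex_core import TimexType
from .type_features import FeatureVector

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "fit",
    "predict",
    "predict_many",
    "cross_validate",
    "save_model",
    "load_model",
]

ALGORITHMS = ("knn_projected", "knn", "logistic", "decision_stub_ensemble")


@dataclass(frozen=True)
class ClassifierConfig:
    algorithm: str = "knn_projected"
    k: int = 1
    projection_dim: int = 32
    seed: int = 0
    # "gaussian" (seeded random matrix) or "identity" (no-op projection, the
    # limit in which knn_projected coincides with plain knn)
    projection: str = "gaussian"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.k < 1 or self.projection_dim < 1:
            raise ValueError("k and projection_dim must be >= 1")
        if self.projection not in ("gaussian", "identity"):
            raise ValueError(f"unknown projection {self.projection!r}")


@dataclass
class TrainedModel:
    config: ClassifierConfig
    feature_names: list[str]
    labels: list[str]  # training labels, in training order
    X: np.ndarray  # training matrix (projected for knn_projected)
    projection: Optional[np.ndarray] = None
    sk_model: object = None  # fitted sklearn estimator for non-KNN algorithms
    classes: list[str] = field(default_factory=list)


def _feature_matrix(
    vectors: Sequence[FeatureVector], feature_names: Sequence[str]
) -> np.ndarray:
    index = {name: j for j, name in enumerate(feature_names)}
    X = np.zeros((len(vectors), len(feature_names)))
    for i, fv in enumerate(vectors):
        for name, value in fv.to_features().items():
            j = index.get(name)
            if j is not None:  # unseen features of probe vectors are ignored
                X[i, j] = value
    return X


def fit(vectors: Sequence[FeatureVector], cfg: ClassifierConfig) -> TrainedModel:
    """Train a model on labeled feature vectors; deterministic given seed."""
    if not vectors:
        raise ValueError("empty training set")
    if any(fv.label is None for fv in vectors):
        raise ValueError("all training vectors must carry a label")
    feature_names = sorted({name for fv in vectors for name in fv.to_features()})
    labels = [fv.label.value for fv in vectors]
    X = _feature_matrix(vectors, feature_names)
    projection = None
    sk_model = None
    if cfg.algorithm == "knn_projected":
        d = len(feature_names)
        if cfg.projection == "identity":
            projection = np.eye(d)
        else:
            rng = np.random.default_rng(cfg.seed)
            projection = rng.normal(size=(d, cfg.projection_dim)) / np.sqrt(
                cfg.projection_dim
            )
        X = X @ projection
    elif cfg.algorithm == "logistic":
        from sklearn.linear_model import LogisticRegression

        sk_model = LogisticRegression(max_iter=2000, random_state=cfg.seed)
        sk_model.fit(X, labels)
    elif cfg.algorithm == "decision_stub_ensemble":
        from sklearn.ensemble import AdaBoostClassifier
        from sklearn.tree import DecisionTreeClassifier

        sk_model = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=50,
            random_state=cfg.seed,
        )
        sk_model.fit(X, labels)
    return TrainedModel(
        config=cfg,
        feature_names=feature_names,
        labels=labels,
        X=X,
        projection=projection,
        sk_model=sk_model,
        classes=sorted(set(labels)),
    )


def _knn_vote(model: TrainedModel, x: np.ndarray) -> str:
    d2 = np.sum((model.X - x) ** 2, axis=1)
    k = min(model.config.k, len(model.labels))
    # order neighbors by (distance, training index): deterministic ties
    order = np.lexsort((np.arange(len(d2)), d2))[:k]
    votes = Counter(model.labels[i] for i in order)
    top = max(votes.values())
    tied = {lab for lab, n in votes.items() if n == top}
    for i in order:  # tie broken by the smallest-index neighbor
        if model.labels[i] in tied:
            return model.labels[i]
    raise AssertionError("unreachable")


def predict(model: TrainedModel, fv: FeatureVector) -> TimexType:
    return predict_many(model, [fv])[0]


def predict_many(model: TrainedModel, vectors: Sequence[FeatureVector]) -> list[TimexType]:
    X = _feature_matrix(vectors, model.feature_names)
    if model.projection is not None:
        X = X @ model.projection
    if model.sk_model is not None:
        return [TimexType(lab) for lab in model.sk_model.predict(X)]
    return [TimexType(_knn_vote(model, x)) for x in X]


def cross_validate(
    vectors: Sequence[FeatureVector],
    cfg: ClassifierConfig,
    folds: int = 10,
    seed: int = 0,
    mf_mode: str = "mean_f1",
) -> EvalReport:
    """K-fold cross-validation with seeded shuffling; macro metrics are
    computed over the pooled out-of-fold predictions."""
    n = len(vectors)
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds number of vectors ({n})")
    labels = [fv.label.value for fv in vectors]
    from sklearn.model_selection import KFold, StratifiedKFold

    min_class = min(Counter(labels).values())
    if min_class >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    gold, pred = [], []
    for train_idx, test_idx in splitter.split(np.zeros(n), labels):
        model = fit([vectors[i] for i in train_idx], cfg)
        out = predict_many(model, [vectors[i] for i in test_idx])
        gold.extend(labels[i] for i in test_idx)
        pred.extend(t.value for t in out)
    mp, mr, mf, per_class = macro_metrics(gold, pred, mf_mode=mf_mode)
    return EvalReport(per_class=per_class, MP=mp, MR=mr, MF=mf,
                      counts={"n": n, "folds": folds})


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model (config and seed embedded) as one bundle."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> TrainedModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, TrainedModel):
        raise TypeError("file does not contain a TrainedModel bundle")
    return model
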