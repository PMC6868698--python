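"""Random-forest (default) and SVM classification of encoder features."""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = ["ClassifierConfig", "train_classifier", "score_pairs"]


@dataclass(frozen=True)
class ClassifierConfig:
    """Classifier family and hyperparameters.

    The random forest (500 trees, unlimited depth, sqrt features per split)
    is the production classifier; the RBF support-vector machine is kept as
    the comparison baseline.
    """

    backend: str = "random_forest"  # "random_forest" | "svm"
    n_trees: int = 500
    max_depth: int | None = None
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("random_forest", "svm"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def with_seed(self, seed: int) -> "ClassifierConfig":
        return replace(self, seed=seed)


def train_classifier(features: np.ndarray, labels, cfg: ClassifierConfig = ClassifierConfig()):
    """Fit the configured classifier on feature vectors; reproducible per seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires both positive and negative examples")
    if counts.min() / counts.sum() < 0.3:
        logger.warning(
            "strongly imbalanced labels (%s); balanced negative sampling is recommended",
            dict(zip(classes.tolist(), counts.tolist())),
        )
    if cfg.backend == "random_forest":
        model = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_depth=cfg.max_depth,
            max_features="sqrt",
            random_state=cfg.seed,
            n_jobs=1,
        )
    else:
        model = SVC(
            kernel=cfg.svm_kernel, C=cfg.svm_c, probability=True, random_state=cfg.seed
        )
    model.fit(X, y)
    return model


def score_pairs(model, features: np.ndarray) -> np.ndarray:
    """Association probability for each feature vector (probability of class 1)."""
    X = np.asarray(features, dtype=float)
    proba = model.predict_proba(X)
    pos = list(model.classes_).index(1)
    return proba[:, pos]
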