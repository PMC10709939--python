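"""The four classifier families on the selected-gene feature matrix.

The deep feedforward network (ReLU hidden blocks with batch normalization and
dropout, sigmoid output, Adam at learning rate 0.001, binary cross-entropy)
is implemented in :mod:`lmsdiag._nn`.  The SVM, random-forest, and
gradient-boosting baselines wrap scikit-learn; only the hyperparameters named
in their search spaces are exposed for tuning, everything else keeps the
library defaults.

Features are always ``samples x selected genes``, and a trained classifier
stores its gene order: predictions demand exactly those genes in that order.
Probabilities at or above the decision threshold (0.5) are called
leiomyosarcoma.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.svm import SVC

from ._nn import FeedForwardNet
from .datamodel import ExpressionMatrix

__all__ = [
    "DnnConfig",
    "TrainedClassifier",
    "FAMILIES",
    "train_dnn",
    "train_baseline",
    "predict_proba",
    "classify",
    "features_from_matrix",
    "save_classifier",
    "load_classifier",
]

FAMILIES = ("dnn", "svm", "rf", "gb")

DNN_LEARNING_RATE = 0.001


@dataclass(frozen=True)
class DnnConfig:
    """Network hyperparameters, each constrained to its search range."""

    dropout_rate: float = 0.3
    n_hidden_layers: int = 3
    n_hidden_nodes: int = 16
    batch_size: int = 16
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.1 <= self.dropout_rate <= 0.7:
            raise ValueError(f"dropout_rate {self.dropout_rate} outside [0.1, 0.7]")
        if not 2 <= self.n_hidden_layers <= 8:
            raise ValueError(f"n_hidden_layers {self.n_hidden_layers} outside [2, 8]")
        if not 2 <= self.n_hidden_nodes <= 32:
            raise ValueError(f"n_hidden_nodes {self.n_hidden_nodes} outside [2, 32]")
        if not 8 <= self.batch_size <= 64:
            raise ValueError(f"batch_size {self.batch_size} outside [8, 64]")
        if not 30 <= self.epochs <= 200:
            raise ValueError(f"epochs {self.epochs} outside [30, 200]")


@dataclass
class TrainedClassifier:
    family: str
    config: dict
    model: object
    feature_gene_order: list[str]
    decision_threshold: float = 0.5


def _check_training_inputs(features: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(f"features shape {X.shape} incompatible with {y.size} labels")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    classes, counts = np.unique(y, return_counts=True)
    if classes.tolist() != [0, 1]:
        raise ValueError("labels must contain both classes (0 and 1)")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    return X, y


def train_dnn(
    features: np.ndarray,
    labels: np.ndarray,
    config: DnnConfig | None = None,
    feature_gene_order: list[str] | None = None,
) -> TrainedClassifier:
    """Train the feedforward network on a samples x genes feature matrix.

    Deterministic given ``config.seed`` under single-threaded execution.
    """
    config = config or DnnConfig()
    X, y = _check_training_inputs(features, labels)
    net = FeedForwardNet(
        n_features=X.shape[1],
        n_hidden_layers=config.n_hidden_layers,
        n_hidden_nodes=config.n_hidden_nodes,
        dropout_rate=config.dropout_rate,
        seed=config.seed,
    )
    net.fit(X, y, epochs=config.epochs, batch_size=config.batch_size,
            learning_rate=DNN_LEARNING_RATE)
    genes = feature_gene_order or [f"f{i}" for i in range(X.shape[1])]
    return TrainedClassifier("dnn", asdict(config), net, list(genes))


def _make_baseline(family: str, config: dict, seed: int):
    if family == "svm":
        params = {k: config[k] for k in ("kernel", "C", "gamma") if k in config}
        return SVC(probability=True, random_state=seed, **params)
    if family == "rf":
        params = {
            k: config[k]
            for k in ("n_estimators", "max_depth", "max_features")
            if k in config
        }
        return RandomForestClassifier(random_state=seed, **params)
    if family == "gb":
        params = {
            k: config[k]
            for k in ("learning_rate", "n_estimators", "max_depth", "max_features")
            if k in config
        }
        return GradientBoostingClassifier(random_state=seed, **params)
    raise ValueError(f"unknown classifier family {family!r}")


def train_baseline(
    family: str,
    features: np.ndarray,
    labels: np.ndarray,
    config: dict | None = None,
    seed: int = 0,
    feature_gene_order: list[str] | None = None,
) -> TrainedClassifier:
    """Fit an SVM / random-forest / gradient-boosting baseline."""
    config = dict(config or {})
    X, y = _check_training_inputs(features, labels)
    model = _make_baseline(family, config, seed)
    with warnings.catch_warnings():
        # SVC(probability=True) is the documented probability route here;
        # sklearn 1.9 deprecation noise is not actionable for callers.
        warnings.filterwarnings("ignore", category=FutureWarning)
        model.fit(X, y)
    genes = feature_gene_order or [f"f{i}" for i in range(X.shape[1])]
    return TrainedClassifier(family, {**config, "seed": seed}, model, list(genes))


def features_from_matrix(model: TrainedClassifier, matrix: ExpressionMatrix) -> np.ndarray:
    """Extract a samples x genes feature array in the classifier's gene order."""
    missing = [g for g in model.feature_gene_order if g not in set(matrix.gene_ids)]
    if missing:
        raise KeyError(f"matrix is missing classifier feature genes: {missing}")
    return matrix.subset_genes(list(model.feature_gene_order)).values.T


def _coerce_features(model: TrainedClassifier, features) -> np.ndarray:
    if isinstance(features, ExpressionMatrix):
        if list(features.gene_ids) != list(model.feature_gene_order):
            raise ValueError(
                "feature gene order mismatch; use features_from_matrix to align"
            )
        X = features.values.T
    else:
        X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_gene_order):
        raise ValueError(
            f"expected {len(model.feature_gene_order)} features, got shape {X.shape}"
        )
    return X


def predict_proba(model: TrainedClassifier, features) -> np.ndarray:
    """Per-sample leiomyosarcoma probability in [0, 1]."""
    X = _coerce_features(model, features)
    if model.family == "dnn":
        return model.model.predict_proba(X)
    return model.model.predict_proba(X)[:, 1]


def classify(model: TrainedClassifier, features) -> np.ndarray:
    """Binary call: positive (1, leiomyosarcoma) iff probability >= threshold."""
    p = predict_proba(model, features)
    return (p >= model.decision_threshold).astype(int)


def save_classifier(model: TrainedClassifier, directory: str | Path) -> None:
    """Persist a classifier bundle (JSON metadata; DNN weights as JSON,
    scikit-learn state pickled)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "family": model.family,
        "config": model.config,
        "feature_gene_order": model.feature_gene_order,
        "decision_threshold": model.decision_threshold,
    }
    (d / "classifier.json").write_text(json.dumps(meta, indent=1))
    if model.family == "dnn":
        (d / "weights.json").write_text(json.dumps(model.model.state_dict()))
    else:
        (d / "model.pkl").write_bytes(pickle.dumps(model.model))


def load_classifier(directory: str | Path) -> TrainedClassifier:
    d = Path(directory)
    meta = json.loads((d / "classifier.json").read_text())
    if meta["family"] == "dnn":
        net = FeedForwardNet.from_state_dict(json.loads((d / "weights.json").read_text()))
        fitted: object = net
    else:
        fitted = pickle.loads((d / "model.pkl").read_bytes())
    return TrainedClassifier(
        meta["family"], meta["config"], fitted, meta["feature_gene_order"],
        meta["decision_threshold"],
    )
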