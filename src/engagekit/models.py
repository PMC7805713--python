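"""Engagement classifiers: the Conv1D network and classical baselines.

All classifiers consume a :class:`~engagekit.dataset.WindowedDataset` and
predict the 7-level engagement class of each window.  The convolutional
network operates on the (L, 71) sequence directly; the classical baselines
(SVC, random forest, decision tree, k-nearest-neighbors) flatten each window
to an L*71 vector first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .cnn import Conv1DNet
from .dataset import N_FEATURES, WindowedDataset
from .engagement import N_CLASSES
from .errors import ConfigError, EmptyDatasetError, ShapeError

BASELINE_KINDS = ("SVC", "RF", "DT", "KNN")
ALL_KINDS = ("CNN",) + BASELINE_KINDS


@dataclass
class CnnSpec:
    """Hyperparameters of the convolutional engagement classifier."""

    conv_filters: tuple[int, int] = (64, 128)
    kernel_size: int = 3
    dropout: float = 0.20
    dense_sizes: tuple[int, ...] = (256, 256, 7)
    seq_len: int = 5
    n_features: int = N_FEATURES
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int = 64
    early_stopping_patience: int | None = 12
    class_weighting: bool = True

    def __post_init__(self):
        if self.dense_sizes[-1] != N_CLASSES:
            raise ConfigError(
                f"final dense size must be {N_CLASSES} (engagement classes), "
                f"got {self.dense_sizes[-1]}"
            )
        if not 0 <= self.dropout < 1:
            raise ConfigError(f"dropout {self.dropout} outside [0, 1)")


def build_cnn(spec: CnnSpec | None = None, seed: int = 0) -> Conv1DNet:
    """Instantiate an untrained network from a spec (deterministic in seed)."""
    spec = spec or CnnSpec()
    return Conv1DNet(
        input_shape=(spec.seq_len, spec.n_features),
        conv_filters=spec.conv_filters,
        kernel_size=spec.kernel_size,
        dropout=spec.dropout,
        dense_sizes=spec.dense_sizes,
        learning_rate=spec.learning_rate,
        seed=seed,
    )


class _ConstantModel:
    """Degenerate fallback when training data holds a single class."""

    def __init__(self, label: int):
        self.label = label

    def predict(self, X):
        return np.full(len(X), self.label, dtype=int)


@dataclass
class TrainedModel:
    """A fitted classifier plus its training provenance."""

    kind: str
    model: object
    seed: int
    history: pd.DataFrame | None = None  # per-epoch curves, CNN only
    seq_len: int = 5
    n_features: int = N_FEATURES
    extra: dict = field(default_factory=dict)


def class_weights(labels: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights over the 7 classes (mean 1 on present classes).

    Counters the heavy imbalance of engagement levels: mid levels dominate a
    session while the extremes (0 and 6) are rare.
    """
    counts = np.bincount(labels, minlength=N_CLASSES).astype(float)
    present = counts > 0
    w = np.zeros(N_CLASSES)
    w[present] = counts[present].sum() / (present.sum() * counts[present])
    return w


def train(
    model: Conv1DNet,
    train_data: WindowedDataset,
    val_data: WindowedDataset | None = None,
    epochs: int | None = None,
    seed: int = 0,
    spec: CnnSpec | None = None,
) -> TrainedModel:
    """Fit the convolutional network; returns model + per-epoch history."""
    spec = spec or CnnSpec()
    if len(train_data) == 0:
        raise EmptyDatasetError("empty training set")
    if len(np.unique(train_data.labels)) == 1:
        warnings.warn("training set holds a single engagement class", stacklevel=2)
    cw = class_weights(train_data.labels) if spec.class_weighting else None
    hist = model.fit(
        train_data.sequences,
        train_data.labels,
        X_val=val_data.sequences if val_data is not None and len(val_data) else None,
        y_val=val_data.labels if val_data is not None and len(val_data) else None,
        epochs=spec.epochs if epochs is None else epochs,
        batch_size=spec.batch_size,
        class_weights=cw,
        early_stopping_patience=spec.early_stopping_patience,
        seed=seed,
    )
    return TrainedModel(
        kind="CNN",
        model=model,
        seed=seed,
        history=pd.DataFrame(hist),
        seq_len=model.input_shape[0],
        n_features=model.input_shape[1],
    )


def _flatten(data: WindowedDataset) -> np.ndarray:
    return data.sequences.reshape(len(data), -1)


def make_baseline(kind: str, seed: int = 0):
    """Default-configured classical classifier (hyperparameters documented)."""
    if kind == "SVC":
        return SVC(C=1.0, kernel="rbf", random_state=seed)
    if kind == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if kind == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if kind == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    raise ConfigError(f"unknown baseline kind: {kind!r} (choose from {BASELINE_KINDS})")


def train_baseline(kind: str, train_data: WindowedDataset, seed: int = 0) -> TrainedModel:
    """Fit one classical baseline on flattened windows."""
    if len(train_data) == 0:
        raise EmptyDatasetError("empty training set")
    X = _flatten(train_data)
    y = train_data.labels
    if len(np.unique(y)) == 1:
        warnings.warn("training set holds a single engagement class", stacklevel=2)
        clf: object = _ConstantModel(int(y[0]))
    else:
        clf = make_baseline(kind, seed)
        clf.fit(X, y)
    return TrainedModel(
        kind=kind,
        model=clf,
        seed=seed,
        seq_len=train_data.seq_len,
        n_features=train_data.sequences.shape[-1],
    )


def predict(trained: TrainedModel, data: WindowedDataset) -> np.ndarray:
    """Class index (0..6) per window; empty input gives an empty output."""
    if len(data) == 0:
        return np.zeros(0, dtype=int)
    if data.seq_len != trained.seq_len or data.sequences.shape[-1] != trained.n_features:
        raise ShapeError(
            f"model expects (N, {trained.seq_len}, {trained.n_features}), "
            f"got {data.sequences.shape}"
        )
    if trained.kind == "CNN":
        return trained.model.predict(data.sequences)
    return np.asarray(trained.model.predict(_flatten(data)), dtype=int)


def predict_proba(trained: TrainedModel, data: WindowedDataset) -> np.ndarray:
    """Normalized class scores (CNN only)."""
    if trained.kind != "CNN":
        raise ConfigError("class scores are available for the CNN only")
    return trained.model.predict_proba(data.sequences)
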