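"""Gesture classification: a scikit-learn estimator around :class:`GestureNet`.

The estimator follows the usual fit/predict contract so it composes with
sklearn pipelines and model selection; ``build_network`` / ``train`` /
``predict`` remain as thin functional wrappers for script use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .cnn import GestureNet, softmax

__all__ = ["TrainConfig", "GestureCNNClassifier", "build_network", "train", "predict"]


@dataclass
class TrainConfig:
    """Training hyperparameters (the source task states none; these are the
    package defaults, fixed in config for reproducibility)."""

    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


class GestureCNNClassifier(ClassifierMixin, BaseEstimator):
    """CNN classifier for 50x50 grayscale gesture images.

    Parameters
    ----------
    classes : sequence of labels or None
        The full class set the network is built for.  None infers the set
        from the training labels.  Passing the 29 alphabet labels while
        training on a subset (e.g. a skeleton variant without NOTHING) is
        supported: unused outputs simply receive no gradient mass.
    epochs, batch_size, learning_rate, optimizer, seed
        Training hyperparameters; ``optimizer`` is "adam" or "sgd".
    vmax : float
        Input intensity ceiling; images are scaled from [0, vmax] to [0, 1]
        before the first layer.
    validation_fraction : float
        Held-out fraction used only to log per-epoch validation accuracy;
        0 disables the split.

    Attributes
    ----------
    classes_ : ndarray
        Class labels in network-output order.
    net_ : GestureNet
        The fitted network.
    history_ : DataFrame
        Columns epoch, loss (and val_accuracy when a split is used).
    n_parameters_ : int
        Trainable parameter count (68,045 for 29 classes).
    """

    def __init__(self, classes=None, epochs: int = 20, batch_size: int = 32,
                 learning_rate: float = 1e-3, optimizer: str = "adam",
                 seed: int = 0, vmax: float = 255.0,
                 validation_fraction: float = 0.0):
        self.classes = classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.optimizer = optimizer
        self.seed = seed
        self.vmax = vmax
        self.validation_fraction = validation_fraction

    # -- helpers ----------------------------------------------------------

    def _as_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape == (50, 50):
            X = X[None]
        elif X.ndim == 2 and X.shape[1] == 2500:
            X = X.reshape(-1, 50, 50)
        if X.ndim == 4 and X.shape[-1] == 1:
            X = X[..., 0]
        if X.ndim != 3 or X.shape[1:] != (50, 50):
            raise ValueError(
                f"expected images of shape (n, 50, 50) or (n, 2500), got {X.shape}"
            )
        return X / self.vmax

    def fit(self, X, y):
        X = self._as_images(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")
        if self.classes is not None:
            self.classes_ = np.asarray(self.classes)
            extra = set(np.unique(y)) - set(self.classes_.tolist())
            if extra:
                raise ValueError(f"labels outside the class set: {sorted(extra)}")
        else:
            self.classes_ = np.unique(y)
        class_index = {c: i for i, c in enumerate(self.classes_.tolist())}
        y_idx = np.array([class_index[label] for label in y.tolist()])

        cfg = TrainConfig(self.epochs, self.batch_size, self.learning_rate,
                          self.optimizer, self.seed)
        rng = np.random.default_rng(cfg.seed)
        net = GestureNet(n_classes=len(self.classes_), seed=cfg.seed)

        n = len(X)
        if self.validation_fraction > 0 and n >= 10:
            perm = rng.permutation(n)
            n_val = max(1, int(round(self.validation_fraction * n)))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
        else:
            tr_idx, val_idx = np.arange(n), np.array([], dtype=int)

        rows = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(tr_idx))
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = tr_idx[order[start : start + cfg.batch_size]]
                loss = net.loss_and_grads(X[batch], y_idx[batch])
                if cfg.optimizer == "adam":
                    net.adam_step(lr=cfg.learning_rate)
                else:
                    net.sgd_step(lr=cfg.learning_rate)
                losses.append(loss)
            row = {"epoch": epoch + 1, "loss": float(np.mean(losses))}
            if len(val_idx):
                pv = net.predict_proba(X[val_idx])
                row["val_accuracy"] = float(
                    (pv.argmax(axis=1) == y_idx[val_idx]).mean()
                )
            rows.append(row)

        self.net_ = net
        self.history_ = pd.DataFrame(rows)
        self.n_parameters_ = net.n_parameters()
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        return self.net_.predict_proba(self._as_images(X))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # argmax breaks ties at the lowest class index
        return self.classes_[proba.argmax(axis=1)]

    def save(self, path) -> None:
        check_is_fitted(self, "net_")
        state = self.net_.state_dict()
        state["classes"] = np.asarray(self.classes_)
        state["vmax"] = np.array(self.vmax)
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "GestureCNNClassifier":
        data = np.load(path, allow_pickle=False)
        clf = cls(classes=data["classes"].tolist(), vmax=float(data["vmax"]))
        clf.classes_ = data["classes"]
        net = GestureNet(n_classes=len(clf.classes_))
        for name, layer in zip(["conv1", "conv2", "conv3", "fc1", "fc2"],
                               net._param_layers):
            layer.W = data[f"{name}.W"].astype(net.dtype)
            layer.b = data[f"{name}.b"].astype(net.dtype)
        clf.net_ = net
        clf.n_parameters_ = net.n_parameters()
        return clf


# -- functional wrappers --------------------------------------------------


def build_network(n_classes: int = 29, seed: int = 0) -> GestureNet:
    """The realized network; shape chain and parameter count are asserted
    at construction time."""
    return GestureNet(n_classes=n_classes, seed=seed)


def train(X, y, cfg: TrainConfig | None = None, classes=None,
          vmax: float = 255.0) -> GestureCNNClassifier:
    """Fit a classifier on images X (n, 50, 50) with labels y."""
    cfg = cfg or TrainConfig()
    clf = GestureCNNClassifier(
        classes=classes, epochs=cfg.epochs, batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate, optimizer=cfg.optimizer,
        seed=cfg.seed, vmax=vmax,
    )
    return clf.fit(X, y)


def predict(clf: GestureCNNClassifier, image: np.ndarray):
    """Label and probability vector for a single 50x50 image."""
    proba = clf.predict_proba(np.asarray(image)[None] if np.asarray(image).ndim == 2
                              else image)
    return clf.classes_[int(proba[0].argmax())], proba[0]
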