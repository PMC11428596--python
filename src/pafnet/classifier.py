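"""Scikit-learn estimator wrapping the 1D CNN.

``PAFNetClassifier`` follows the fit/predict contract, so it composes with
sklearn model selection and pipelines. Rows of ``X`` are windows of N
consecutive R-R intervals in seconds; ``y`` is binary with 1 (PAFN,
pre-AF rhythm) as the positive class.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import model as _model
from . import nn

__all__ = ["PAFNetClassifier", "save_model", "load_model"]


class PAFNetClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier over fixed-length R-R interval windows.

    Parameters
    ----------
    epochs : int, default=9
        Training epochs.
    batch_size : int, default=512
        Minibatch size; the last short batch of an epoch is kept.
    learning_rate : float, default=1e-3
        Adam learning rate (binary cross-entropy loss).
    threshold : float, default=0.5
        Probability threshold used by :meth:`predict`.
    random_state : int or None, default=None
        Seeds weight initialization, epoch shuffling and dropout.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels; the larger label is the positive class.
    n_features_in_ : int
        Window size N the network was built for.
    spec_ : ModelSpec
        Resolved layer list.
    net_ : Sequential
        The trained network.
    history_ : list of float
        Mean training loss per epoch.
    """

    def __init__(self, epochs: int = 9, batch_size: int = 512,
                 learning_rate: float = 1e-3, threshold: float = 0.5,
                 random_state: int | None = None):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float32)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValueError(f"binary classifier requires exactly 2 classes, got {list(self.classes_)}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        self.n_features_in_ = X.shape[1]
        y01 = (y == self.classes_[1]).astype(np.float32)

        seed = 0 if self.random_state is None else int(self.random_state)
        self.spec_ = _model.build_pafnet(self.n_features_in_)
        self.net_ = _model.instantiate(self.spec_, seed=seed)
        rng = np.random.default_rng(seed + 1)
        opt = nn.Adam(self.net_.params(), lr=self.learning_rate)

        n = len(X)
        self.history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                xb = X[idx][:, None, :]  # (B, 1, N)
                yb = y01[idx][:, None]
                p = self.net_.forward(xb, training=True)
                loss = nn.bce_loss(p, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged: non-finite loss {loss} at step {len(losses)}")
                self.net_.backward(nn.bce_grad(p, yb))
                opt.step()
                losses.append(loss)
            self.history_.append(float(np.mean(losses)))
        return self

    def _proba_pos(self, X: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        out = np.empty(len(X), dtype=np.float64)
        for lo in range(0, len(X), batch_size):
            xb = X[lo : lo + batch_size][:, None, :]
            out[lo : lo + len(xb)] = self.net_.forward(xb, training=False)[:, 0]
        return out

    def predict_proba(self, X):
        check_is_fitted(self)
        X = check_array(X, dtype=np.float32)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"X has {X.shape[1]} features, expected {self.n_features_in_}")
        p = self._proba_pos(X)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= self.threshold).astype(int)]


def save_model(clf: PAFNetClassifier, path: str | Path) -> Path:
    """Persist a fitted classifier: weights (npz) + layer manifest + meta."""
    check_is_fitted(clf)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"arr_{i}": a for i, a in enumerate(clf.net_.state_arrays())}
    meta = {
        "n_features_in": int(clf.n_features_in_),
        "classes": [int(c) for c in clf.classes_],
        "params": {k: v for k, v in clf.get_params().items()},
        "history": clf.history_,
    }
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **arrays)
    path.with_suffix(".manifest.txt").write_text(clf.spec_.to_manifest())
    return path


def load_model(path: str | Path) -> PAFNetClassifier:
    """Restore a classifier saved with :func:`save_model`."""
    path = Path(path)
    z = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(z["__meta__"]).decode())
    clf = PAFNetClassifier(**meta["params"])
    clf.classes_ = np.array(meta["classes"])
    clf.n_features_in_ = meta["n_features_in"]
    clf.history_ = meta["history"]
    clf.spec_ = _model.build_pafnet(clf.n_features_in_)
    clf.net_ = _model.instantiate(clf.spec_, seed=0)
    n_arrays = len(clf.net_.state_arrays())
    clf.net_.load_state_arrays([z[f"arr_{i}"] for i in range(n_arrays)])
    return clf
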