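"""Stratified ten-fold cross-validation and fold-ensemble prediction.

One network is trained per fold on nine tenths of the windows; its
confusion counts and sensitivity/specificity/accuracy are computed on the
held-out tenth. At test time the k fold models act as an ensemble: their
sigmoid outputs are averaged and thresholded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .classifier import PAFNetClassifier
from .evaluation import MetricSet, metrics_from_counts
from .windows import WindowDataset

__all__ = ["TrainConfig", "FoldResult", "stratified_folds", "train_cv", "ensemble_predict"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 9
    batch_size: int = 512
    k_folds: int = 10
    seed: int = 0
    learning_rate: float = 1e-3
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError(f"k_folds must be >= 2, got {self.k_folds}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")


@dataclass
class FoldResult:
    """Held-out confusion counts and metrics for one fold."""

    fold: int
    tp: int
    fn: int
    tn: int
    fp: int
    metrics: MetricSet
    model: PAFNetClassifier = field(repr=False, default=None)


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Split indices into k disjoint stratified blocks.

    Within each class the indices are shuffled under the seed and dealt
    into k near-equal contiguous chunks, so every block's class ratio is
    within one percentage point of the global ratio. Deterministic under
    the seed; a class with fewer than k members is an error.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present to stratify")
    rng = np.random.default_rng(seed)
    blocks: list[list[np.ndarray]] = [[] for _ in range(k)]
    for c in classes:
        idx = np.flatnonzero(y == c)
        if len(idx) < k:
            raise ValueError(f"class {c!r} has {len(idx)} members, fewer than k={k}")
        rng.shuffle(idx)
        for j, chunk in enumerate(np.array_split(idx, k)):
            blocks[j].append(chunk)
    return [np.sort(np.concatenate(parts)) for parts in blocks]


def _confusion(y_true01: np.ndarray, y_pred01: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true01 == 1) & (y_pred01 == 1)))
    fn = int(np.sum((y_true01 == 1) & (y_pred01 == 0)))
    tn = int(np.sum((y_true01 == 0) & (y_pred01 == 0)))
    fp = int(np.sum((y_true01 == 0) & (y_pred01 == 1)))
    return tp, fn, tn, fp


def train_cv(dataset: WindowDataset, config: TrainConfig | None = None) -> list[FoldResult]:
    """Train k models under stratified k-fold cross-validation.

    Each fold's metrics come from its own model evaluated on its held-out
    block at the configured threshold. Fold assignment is deterministic
    under the seed.
    """
    cfg = config or TrainConfig()
    X, y = dataset.X, dataset.y
    folds = stratified_folds(y, cfg.k_folds, cfg.seed)
    results: list[FoldResult] = []
    all_idx = np.arange(len(y))
    for j, val_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[val_idx] = False
        train_idx = all_idx[train_mask]
        clf = PAFNetClassifier(epochs=cfg.epochs, batch_size=cfg.batch_size,
                               learning_rate=cfg.learning_rate, threshold=cfg.threshold,
                               random_state=cfg.seed + j)
        clf.fit(X[train_idx], y[train_idx])
        p = clf.predict_proba(X[val_idx])[:, 1]
        pred = (p >= cfg.threshold).astype(int)
        tp, fn, tn, fp = _confusion(y[val_idx], pred)
        m = metrics_from_counts(tp, fn, tn, fp)
        logger.info("fold %d: Sen %.4f Spe %.4f Acc %.4f (val n=%d)",
                    j + 1, m.sen, m.spe, m.acc, len(val_idx))
        results.append(FoldResult(fold=j + 1, tp=tp, fn=fn, tn=tn, fp=fp,
                                  metrics=m, model=clf))
    return results


def ensemble_predict(models: list[PAFNetClassifier], X: np.ndarray,
                     k_expected: int = 10) -> np.ndarray:
    """Mean positive-class probability over the fold models.

    The model count must equal the expected ensemble size (the number of
    cross-validation folds).
    """
    if len(models) != k_expected:
        raise ValueError(f"expected {k_expected} fold models, got {len(models)}")
    X = np.asarray(X, dtype=np.float32)
    probs = np.stack([m.predict_proba(X)[:, 1] for m in models])
    return probs.mean(axis=0)
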