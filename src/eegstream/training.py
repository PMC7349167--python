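"""Training and evaluation protocol for the 3D-CNN classifiers.

Plain minibatch SGD (batch 16) on softmax cross-entropy, with the learning
rate starting at 0.01 and divided by 10 every 10 epochs, for 30 epochs.
During training each minibatch is augmented with additive Gaussian noise of
zero mean and unit variance; augmentation and dropout are disabled at
evaluation.  Model selection is 5-fold cross-validation with folds drawn at
random over streams — streams from one trial may land in different folds,
which matches the protocol this package reproduces but is leakage-prone; a
trial-grouped split is available through ``groups``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.model_selection import GroupKFold, KFold, StratifiedKFold

from . import nn

__all__ = [
    "TrainConfig",
    "FoldResult",
    "lr_at_epoch",
    "augment_gaussian",
    "kfold_split",
    "train_model",
    "evaluate",
    "cross_validate",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization protocol knobs with the published defaults."""

    batch_size: int = 16
    initial_lr: float = 0.01
    lr_decay_factor: float = 10.0
    lr_decay_every: int = 10
    epochs: int = 30
    momentum: float = 0.0
    noise_sigma: float = 1.0
    augment: bool = True
    seed: int = 0
    k_folds: int = 5
    task: str = "valence"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class FoldResult:
    """Outcome of one cross-validation fold."""

    fold_index: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    test_accuracy: float
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.test_accuracy <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test folds overlap")


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Step-decayed learning rate: initial / factor^floor(epoch / every)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return cfg.initial_lr / cfg.lr_decay_factor ** (epoch // cfg.lr_decay_every)


def augment_gaussian(
    batch: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Additive Gaussian noise of standard deviation sigma (training-time only)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return batch
    return batch + sigma * rng.standard_normal(batch.shape).astype(batch.dtype)


def kfold_split(
    n_items: int,
    k: int,
    seed: int,
    stratify_labels: Optional[np.ndarray] = None,
    groups: Optional[np.ndarray] = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random k-fold partition: fold sizes differ by at most one.

    Default is an unstratified shuffled split over items.  ``stratify_labels``
    switches to a label-stratified split; ``groups`` (e.g. trial identifiers)
    keeps all items of a group in the same fold, the leakage-safe option.
    """
    if n_items < k:
        raise ValueError(f"cannot split {n_items} items into {k} folds")
    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        return [(tr, te) for tr, te in splitter.split(np.zeros(n_items), groups=groups)]
    if stratify_labels is not None:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(np.zeros(n_items), stratify_labels)]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(n_items))]


def train_model(
    model: nn.Layer,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[nn.Layer, list[dict]]:
    """Run the SGD protocol on (X, y); returns the model and per-epoch history.

    X is (n, c, t, h, w); y holds integer class labels.  Shuffling,
    augmentation noise and dropout masks all draw from ``rng`` (derived from
    cfg.seed when not given).  ``epochs=0`` returns the model untouched with
    an empty history.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 5:
        raise ValueError("X must be (n, channels, length, height, width)")
    if len(X) != len(y) or len(X) == 0:
        raise ValueError("X and y must be non-empty and aligned")
    rng = rng or np.random.default_rng(cfg.seed)
    nn.set_dropout_rng(model, rng)
    opt = nn.SGD(model.params(), momentum=cfg.momentum)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(len(X))
        losses, correct = [], 0
        t0 = time.perf_counter()
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            if cfg.augment:
                xb = augment_gaussian(xb, cfg.noise_sigma, rng)
            logits = model.forward(xb, training=True)
            loss, grad = nn.softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            model.backward(grad)
            opt.step(lr)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "loss": float(np.mean(losses)),
                "train_accuracy": correct / len(X),
                "seconds": time.perf_counter() - t0,
            }
        )
        logger.debug(
            "epoch %d: lr=%.2g loss=%.4f acc=%.3f",
            epoch, lr, history[-1]["loss"], history[-1]["train_accuracy"],
        )
    return model, history


def predict_logits(
    model: nn.Layer, X: np.ndarray, batch_size: int = 16
) -> np.ndarray:
    """Forward pass in evaluation mode (no dropout, batch-norm running stats)."""
    X = np.asarray(X, dtype=np.float32)
    out = [
        model.forward(X[s : s + batch_size], training=False)
        for s in range(0, len(X), batch_size)
    ]
    return np.concatenate(out, axis=0)


def evaluate(model: nn.Layer, X: np.ndarray, y: np.ndarray, batch_size: int = 16) -> float:
    """Fraction of items whose argmax logit equals the true label."""
    if len(X) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    logits = predict_logits(model, X, batch_size)
    return float((logits.argmax(axis=1) == np.asarray(y)).mean())


def cross_validate(
    model_builder: Callable[[int], nn.Layer],
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    groups: Optional[np.ndarray] = None,
    stratify: bool = False,
) -> tuple[float, list[FoldResult]]:
    """k-fold cross-validation training a fresh model per fold from scratch.

    ``model_builder(seed)`` must return an untrained graph.  The master
    cfg.seed fans out deterministically to the split, each fold's weight
    initialization, and each fold's shuffling/augmentation stream.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    folds = kfold_split(
        len(X),
        cfg.k_folds,
        seed=cfg.seed,
        stratify_labels=y if stratify else None,
        groups=groups,
    )
    results: list[FoldResult] = []
    for i, (train_idx, test_idx) in enumerate(folds):
        model = model_builder(cfg.seed + 1000 * (i + 1))
        fold_rng = np.random.default_rng([cfg.seed, i])
        model, history = train_model(model, X[train_idx], y[train_idx], cfg, fold_rng)
        acc = evaluate(model, X[test_idx], y[test_idx], cfg.batch_size)
        logger.info("fold %d: test accuracy %.4f", i, acc)
        results.append(
            FoldResult(
                fold_index=i,
                train_indices=train_idx,
                test_indices=test_idx,
                test_accuracy=acc,
                loss_history=[h["loss"] for h in history],
            )
        )
    mean_acc = float(np.mean([r.test_accuracy for r in results]))
    return mean_acc, results
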