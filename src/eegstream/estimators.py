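"""scikit-learn style wrappers around the 3D-CNN classifiers.

``C3DClassifier`` and ``R2Plus1DClassifier`` expose fit / predict /
predict_proba / score over 5-D stream tensors (n, 1, t, h, w), so they
compose with ``sklearn.base.clone``, pipelines and model selection.  The
heavy lifting (graph construction, SGD loop) lives in
:mod:`eegstream.models` and :mod:`eegstream.training`.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import models, training

__all__ = ["C3DClassifier", "R2Plus1DClassifier"]


class _Stream3DClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery; subclasses choose the graph builder."""

    def __init__(
        self,
        kernel_temporal_depth: int = 7,
        kernel_spatial: int = 3,
        dropout_keep: float = 0.5,
        batch_size: int = 16,
        initial_lr: float = 0.01,
        lr_decay_factor: float = 10.0,
        lr_decay_every: int = 10,
        epochs: int = 30,
        momentum: float = 0.0,
        noise_sigma: float = 1.0,
        augment: bool = True,
        random_state: int = 0,
    ) -> None:
        self.kernel_temporal_depth = kernel_temporal_depth
        self.kernel_spatial = kernel_spatial
        self.dropout_keep = dropout_keep
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_every = lr_decay_every
        self.epochs = epochs
        self.momentum = momentum
        self.noise_sigma = noise_sigma
        self.augment = augment
        self.random_state = random_state

    # subclasses override
    def _build(self, cfg: models.ModelConfig, seed: int):
        raise NotImplementedError

    def _model_config(self, input_shape, num_classes) -> models.ModelConfig:
        raise NotImplementedError

    def _validate_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 5:
            raise ValueError(
                f"X must be (n, channels, length, height, width); got shape {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Stream3DClassifier":
        X = self._validate_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        cfg = self._model_config(X.shape[1:], len(self.classes_))
        self.model_config_ = cfg
        self.model_ = self._build(cfg, self.random_state)
        train_cfg = training.TrainConfig(
            batch_size=self.batch_size,
            initial_lr=self.initial_lr,
            lr_decay_factor=self.lr_decay_factor,
            lr_decay_every=self.lr_decay_every,
            epochs=self.epochs,
            momentum=self.momentum,
            noise_sigma=self.noise_sigma,
            augment=self.augment,
            seed=self.random_state,
        )
        rng = np.random.default_rng(self.random_state)
        self.model_, self.history_ = training.train_model(
            self.model_, X, y_idx, train_cfg, rng
        )
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        X = self._validate_X(X)
        return training.predict_logits(self.model_, X, self.batch_size)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.decision_function(X)
        shifted = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        logits = self.decision_function(X)
        return self.classes_[logits.argmax(axis=1)]

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted; call fit first")

    @property
    def n_parameters_(self) -> int:
        self._check_fitted()
        return models.count_parameters(self.model_)


class C3DClassifier(_Stream3DClassifier):
    """Plain 3D-CNN (C3D-style) stream classifier."""

    def __init__(
        self,
        block_channels: tuple[int, ...] = (64, 128, 256, 256, 256),
        fc_width: int = 4096,
        kernel_temporal_depth: int = 7,
        kernel_spatial: int = 3,
        dropout_keep: float = 0.5,
        batch_size: int = 16,
        initial_lr: float = 0.01,
        lr_decay_factor: float = 10.0,
        lr_decay_every: int = 10,
        epochs: int = 30,
        momentum: float = 0.0,
        noise_sigma: float = 1.0,
        augment: bool = True,
        random_state: int = 0,
    ) -> None:
        super().__init__(
            kernel_temporal_depth=kernel_temporal_depth,
            kernel_spatial=kernel_spatial,
            dropout_keep=dropout_keep,
            batch_size=batch_size,
            initial_lr=initial_lr,
            lr_decay_factor=lr_decay_factor,
            lr_decay_every=lr_decay_every,
            epochs=epochs,
            momentum=momentum,
            noise_sigma=noise_sigma,
            augment=augment,
            random_state=random_state,
        )
        self.block_channels = block_channels
        self.fc_width = fc_width

    def _model_config(self, input_shape, num_classes) -> models.ModelConfig:
        return models.ModelConfig(
            input_shape=tuple(input_shape),
            num_classes=num_classes,
            kernel_temporal_depth=self.kernel_temporal_depth,
            kernel_spatial=self.kernel_spatial,
            c3d_block_channels=tuple(self.block_channels),
            c3d_fc_width=self.fc_width,
            dropout_keep=self.dropout_keep,
        )

    def _build(self, cfg: models.ModelConfig, seed: int):
        return models.build_c3d(cfg, seed)


class R2Plus1DClassifier(_Stream3DClassifier):
    """Residual (2+1)D factorized-convolution stream classifier."""

    def __init__(
        self,
        block_channels: tuple[int, ...] = (64, 128, 256, 512),
        stem_spatial_channels: int = 45,
        stem_temporal_channels: int = 64,
        fc_width: int = 512,
        kernel_temporal_depth: int = 7,
        kernel_spatial: int = 3,
        dropout_keep: float = 0.5,
        batch_size: int = 16,
        initial_lr: float = 0.01,
        lr_decay_factor: float = 10.0,
        lr_decay_every: int = 10,
        epochs: int = 30,
        momentum: float = 0.0,
        noise_sigma: float = 1.0,
        augment: bool = True,
        random_state: int = 0,
    ) -> None:
        super().__init__(
            kernel_temporal_depth=kernel_temporal_depth,
            kernel_spatial=kernel_spatial,
            dropout_keep=dropout_keep,
            batch_size=batch_size,
            initial_lr=initial_lr,
            lr_decay_factor=lr_decay_factor,
            lr_decay_every=lr_decay_every,
            epochs=epochs,
            momentum=momentum,
            noise_sigma=noise_sigma,
            augment=augment,
            random_state=random_state,
        )
        self.block_channels = block_channels
        self.stem_spatial_channels = stem_spatial_channels
        self.stem_temporal_channels = stem_temporal_channels
        self.fc_width = fc_width

    def _model_config(self, input_shape, num_classes) -> models.ModelConfig:
        return models.ModelConfig(
            input_shape=tuple(input_shape),
            num_classes=num_classes,
            kernel_temporal_depth=self.kernel_temporal_depth,
            kernel_spatial=self.kernel_spatial,
            r21d_block_channels=tuple(self.block_channels),
            r21d_stem_spatial_channels=self.stem_spatial_channels,
            r21d_stem_temporal_channels=self.stem_temporal_channels,
            r21d_fc_width=self.fc_width,
            dropout_keep=self.dropout_keep,
        )

    def _build(self, cfg: models.ModelConfig, seed: int):
        return models.build_r2plus1d(cfg, seed)
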