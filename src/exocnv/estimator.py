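"""Scikit-learn-style estimator wrapping the CNV classifier.

`ExonCNVClassifier` presents the conv/transformer model through the familiar
fit / predict / predict_proba surface so it composes with sklearn pipelines
and model selection. `X` is an (n_windows, window_len) array of normalized,
right-padded depth signals; the per-window chromosome ids travel as a fit
parameter (default: chromosome 1 for all windows).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .labels import CNVClass
from .model import CNVTransformer, ModelConfig
from .training import TrainConfig, _train

__all__ = ["ExonCNVClassifier"]


class ExonCNVClassifier(BaseEstimator, ClassifierMixin):
    """Exon-level CNV caller: NOCALL / DEL / DUP from a read-depth window.

    Parameters mirror the model and optimizer configuration; fitted state
    lives in `model_` (the network) and `train_report_` (per-epoch loss and
    held-out macro-F1). `finetune` continues training from the fitted state
    on new (typically coverage-thinned) windows, returning a new fitted
    estimator, which realizes the two-stage pretrain/fine-tune strategy.

    Examples
    --------
    >>> clf = ExonCNVClassifier(window_len=128, conv_channels=(8, 16),
    ...                         n_transformer_blocks=1, n_heads=2,
    ...                         epochs=2, random_state=0)
    >>> clf.fit(X, y, chromosomes=chrom)          # doctest: +SKIP
    >>> clf.predict_proba(X_low).shape            # doctest: +SKIP
    (n_windows, 3)
    """

    def __init__(self, window_len: int = 1000,
                 conv_channels: tuple[int, int] = (32, 64),
                 kernel_size: int = 3, n_transformer_blocks: int = 3,
                 n_heads: int = 4, ffn_dim: int = 128, dropout: float = 0.1,
                 n_chromosomes: int = 24, learning_rate: float = 5e-5,
                 schedule: str = "cosine_annealing", batch_size: int = 64,
                 epochs: int = 3, class_weights=None, val_fraction: float = 0.1,
                 random_state: int = 0):
        self.window_len = window_len
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.n_transformer_blocks = n_transformer_blocks
        self.n_heads = n_heads
        self.ffn_dim = ffn_dim
        self.dropout = dropout
        self.n_chromosomes = n_chromosomes
        self.learning_rate = learning_rate
        self.schedule = schedule
        self.batch_size = batch_size
        self.epochs = epochs
        self.class_weights = class_weights
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- configuration plumbing -----------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            window_len=self.window_len, conv_channels=tuple(self.conv_channels),
            kernel_size=self.kernel_size,
            n_transformer_blocks=self.n_transformer_blocks,
            n_heads=self.n_heads, ffn_dim=self.ffn_dim, dropout=self.dropout,
            n_chromosomes=self.n_chromosomes)

    def _train_config(self, class_weights=None) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, schedule=self.schedule,
            batch_size=self.batch_size, epochs=self.epochs,
            class_weights=class_weights if class_weights is not None
            else self.class_weights,
            val_fraction=self.val_fraction, seed=self.random_state)

    def _validate(self, X, chromosomes):
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.window_len:
            raise ValueError(f"X has {X.shape[1]} columns, expected window_len="
                             f"{self.window_len}")
        if chromosomes is None:
            chrom = np.ones(len(X), dtype=np.int64)
        else:
            chrom = np.asarray(chromosomes, dtype=np.int64)
            if chrom.shape != (len(X),):
                raise ValueError("chromosomes must be one id per window")
        return X, chrom

    @staticmethod
    def _encode_y(y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "UOS":
            return np.array([int(CNVClass[str(v)]) for v in y], dtype=np.int64)
        return y.astype(np.int64)

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y, chromosomes=None):
        """Pretrain a fresh model on labeled windows."""
        X, chrom = self._validate(X, chromosomes)
        y = self._encode_y(y)
        self.classes_ = np.array([c.name for c in CNVClass])
        self.model_ = CNVTransformer(self._model_config(), seed=self.random_state)
        self.train_report_ = _train(self.model_, X, chrom, y, self._train_config())
        return self

    def finetune(self, X, y, chromosomes=None, class_weights="balanced",
                 epochs: int | None = None) -> "ExonCNVClassifier":
        """Continue training on (thinned window, full-coverage label) pairs.

        Class weighting defaults to inverse-frequency ("balanced") because
        DEL/DUP exons are vastly outnumbered by NOCALL. Returns a new fitted
        estimator; the original is left untouched.
        """
        check_is_fitted(self, "model_")
        X, chrom = self._validate(X, chromosomes)
        y = self._encode_y(y)
        tuned = ExonCNVClassifier(**self.get_params())
        if epochs is not None:
            tuned.epochs = epochs
        tuned.classes_ = self.classes_.copy()
        tuned.model_ = CNVTransformer(self._model_config(), seed=self.random_state)
        tuned.model_.load_state_dict(self.model_.state_dict())
        cfg = tuned._train_config(class_weights=class_weights)
        tuned.train_report_ = _train(tuned.model_, X, chrom, y, cfg)
        return tuned

    def predict_proba(self, X, chromosomes=None) -> np.ndarray:
        check_is_fitted(self, "model_")
        X, chrom = self._validate(X, chromosomes)
        return self.model_.predict_proba(X, chrom, batch_size=self.batch_size)

    def predict(self, X, chromosomes=None) -> np.ndarray:
        """Hard labels as class names; exact ties resolve to NOCALL."""
        probs = self.predict_proba(X, chromosomes)
        labels = []
        for row in probs:
            winners = np.flatnonzero(row == row.max())
            labels.append(CNVClass.NOCALL if len(winners) > 1
                          else CNVClass(int(winners[0])))
        return np.array([l.name for l in labels])
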