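"""Two-stage optimization: pretraining and low-coverage fine-tuning.

The model is first trained on windows whose labels come from conventional
callers on high-coverage data (pretraining), then fine-tuned on pairs of
coverage-thinned windows and the same full-coverage labels, which adapts it
to the sparse, spiky depth signal of degraded low-coverage samples. Both
stages use Adam with a cosine-annealed learning rate; all layers stay
trainable during fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .labels import TrainingPair
from .model import CNVTransformer, ModelConfig
from .nn.autograd import Tensor
from .nn.optim import Adam, cosine_annealing_lr

__all__ = ["TrainConfig", "TrainReport", "classification_loss",
           "pretrain", "finetune", "pairs_to_arrays"]


@dataclass
class TrainConfig:
    """Optimization settings. The full-scale defaults are lr 5e-5 with cosine
    annealing, one pretraining epoch and three fine-tuning epochs; desk-scale
    runs on small synthetic cohorts use more epochs and a larger rate."""

    learning_rate: float = 5e-5
    schedule: str = "cosine_annealing"   # or "constant"
    optimizer: str = "adam"
    batch_size: int = 64
    epochs: int = 3
    class_weights: np.ndarray | str | None = None  # None | "balanced" | 3-vector
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.schedule not in ("cosine_annealing", "constant"):
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class TrainReport:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_macro_f1: list[float] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\tmean_loss\tval_macro_f1\tfinal_lr\n")
            for i, (l, f1, lr) in enumerate(zip(self.epoch_loss,
                                                self.epoch_macro_f1,
                                                self.learning_rates), 1):
                fh.write(f"{i}\t{l:.6f}\t{f1:.6f}\t{lr:.8g}\n")


def classification_loss(probabilities: Tensor | np.ndarray,
                        labels: np.ndarray,
                        class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted multiclass cross-entropy, mean over the batch.

    `probabilities` are post-softmax rows; the loss is
    mean_i w[y_i] * (-log p_i[y_i]), so zero exactly at one-hot correct
    predictions and ln(3) for uniform unweighted predictions.
    """
    if not isinstance(probabilities, Tensor):
        probabilities = Tensor(probabilities)
    labels = np.asarray(labels, dtype=np.int64)
    n = len(labels)
    if n == 0:
        raise ValueError("empty batch")
    picked = probabilities[np.arange(n), labels]
    logp = (picked + 1e-12).log()
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=np.float64)[labels]
        logp = logp * Tensor(w)
    return -logp.mean()


def pairs_to_arrays(pairs: list[TrainingPair]):
    """Stack training pairs into (signals, chromosomes, labels) arrays."""
    X = np.stack([p.window.signal for p in pairs])
    chrom = np.array([p.window.exon.chromosome for p in pairs], dtype=np.int64)
    y = np.array([int(p.label) for p in pairs], dtype=np.int64)
    return X, chrom, y


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of the one-vs-rest F1 of DEL and DUP (NOCALL is the background)."""
    from .evalpop import confusion_and_f1

    return confusion_and_f1(list(y_pred), list(y_true)).macro_f1


def _resolve_class_weights(cfg: TrainConfig, y: np.ndarray) -> np.ndarray | None:
    if cfg.class_weights is None:
        return None
    if isinstance(cfg.class_weights, str):
        if cfg.class_weights != "balanced":
            raise ValueError(f"unknown class_weights {cfg.class_weights!r}")
        counts = np.bincount(y, minlength=3).astype(np.float64)
        counts[counts == 0] = 1.0
        w = len(y) / (3.0 * counts)
        return w
    return np.asarray(cfg.class_weights, dtype=np.float64)


def _train(model: CNVTransformer, X: np.ndarray, chrom: np.ndarray,
           y: np.ndarray, cfg: TrainConfig) -> TrainReport:
    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    # held-out split for per-epoch reporting
    n_val = int(round(cfg.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        raise ValueError("no training examples left after validation split")
    weights = _resolve_class_weights(cfg, y[tr_idx])

    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    steps_per_epoch = int(np.ceil(len(tr_idx) / cfg.batch_size))
    total_steps = steps_per_epoch * cfg.epochs
    report = TrainReport()
    step = 0
    model.train()
    for _ in range(cfg.epochs):
        order = rng.permutation(len(tr_idx))
        losses = []
        lr = cfg.learning_rate
        for b in range(0, len(order), cfg.batch_size):
            idx = tr_idx[order[b:b + cfg.batch_size]]
            probs = model.forward_batch(Tensor(X[idx]), chrom[idx], rng)
            loss = classification_loss(probs, y[idx], weights)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at step {step}; "
                    f"report so far: {report}")
            opt.zero_grad()
            loss.backward()
            lr = (cosine_annealing_lr(cfg.learning_rate, step, total_steps)
                  if cfg.schedule == "cosine_annealing" else cfg.learning_rate)
            opt.step(lr=lr)
            losses.append(loss.item())
            step += 1
        report.epoch_loss.append(float(np.mean(losses)))
        report.learning_rates.append(lr)
        if len(val_idx):
            val_probs = model.predict_proba(X[val_idx], chrom[val_idx],
                                            batch_size=cfg.batch_size)
            report.epoch_macro_f1.append(
                _macro_f1(y[val_idx], val_probs.argmax(axis=1)))
        else:
            report.epoch_macro_f1.append(float("nan"))
        model.train()
    model.eval()
    return report


def pretrain(model_config: ModelConfig, pairs: list[TrainingPair],
             cfg: TrainConfig) -> CNVTransformer:
    """Train a freshly initialized model on labeled high-coverage windows.

    Returns the trained model with its `train_report` attached; deterministic
    for a fixed (data, config, seed) on a single device.
    """
    if not pairs:
        raise ValueError("no training pairs supplied")
    model = CNVTransformer(model_config, seed=cfg.seed)
    X, chrom, y = pairs_to_arrays(pairs)
    model.train_report = _train(model, X, chrom, y, cfg)
    return model


def finetune(model: CNVTransformer, pairs: list[TrainingPair],
             cfg: TrainConfig) -> CNVTransformer:
    """Continue training an initialized model on thinned-window pairs.

    All layers remain trainable (no freezing). The input model is not
    modified; the returned model carries the updated parameters.
    """
    if not pairs:
        raise ValueError("no fine-tuning pairs supplied")
    tuned = CNVTransformer(model.config, seed=cfg.seed)
    tuned.load_state_dict(model.state_dict())
    X, chrom, y = pairs_to_arrays(pairs)
    tuned.train_report = _train(tuned, X, chrom, y, cfg)
    return tuned
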