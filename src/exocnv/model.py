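"""The CNV classifier network.

A per-exon read-depth window is embedded by two 1-D convolutions
(1 -> 32 -> 64 channels, kernel 3, stride 1, each followed by batch
normalization and ReLU), a trainable chromosome-specific classification
token is appended to the embedded sequence, a fixed sinusoidal positional
encoding is added, and the result traverses a cascade of transformer
encoder blocks. The transformed token position is sliced off and passed
through a fully connected head with softmax over the three call classes
(NOCALL, DEL, DUP). The token row carries the chromosome context into the
read-out, which is what lets one shared backbone specialize per chromosome.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .io import ExonWindow
from .labels import CNVClass
from .nn.autograd import Tensor

__all__ = ["ModelConfig", "ForwardTrace", "CNVTransformer", "predict_class",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters. Defaults are the full-scale settings."""

    window_len: int = 1000
    conv_channels: tuple[int, int] = (32, 64)
    kernel_size: int = 3
    stride: int = 1
    n_transformer_blocks: int = 3
    n_heads: int = 4
    ffn_dim: int = 128
    dropout: float = 0.1
    n_chromosomes: int = 24
    n_classes: int = 3

    @property
    def embed_dim(self) -> int:
        return self.conv_channels[1]

    @property
    def seq_len(self) -> int:
        """Transformer sequence length: window positions plus the token."""
        return self.window_len + 1

    def __post_init__(self):
        if self.stride != 1:
            raise ValueError("only stride 1 is supported (length-preserving)")
        for v in (self.window_len, *self.conv_channels, self.kernel_size,
                  self.n_heads, self.ffn_dim, self.n_chromosomes, self.n_classes):
            if v <= 0:
                raise ValueError("all dimensions must be positive")
        if self.n_transformer_blocks < 0:
            raise ValueError("n_transformer_blocks must be >= 0")


@dataclass
class ForwardTrace:
    """Intermediate activations of a single-window forward pass."""

    embedded: np.ndarray      # (window_len, embed_dim), post-conv
    assembled: np.ndarray     # (window_len+1, embed_dim), token + positions added
    transformed: np.ndarray   # (window_len+1, embed_dim), post-transformer
    token_out: np.ndarray     # (embed_dim,)
    probabilities: np.ndarray  # (3,) NOCALL, DEL, DUP

    def __post_init__(self):
        if not np.isclose(self.probabilities.sum(), 1.0, atol=1e-6):
            raise ValueError("probabilities do not sum to 1")


class CNVTransformer(nn.Module):
    """Conv embedding + chromosome token + positional encoding + encoder cascade."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c1, c2 = config.conv_channels
        self.conv1 = nn.Conv1d(1, c1, config.kernel_size, rng)
        self.bn1 = nn.BatchNorm1d(c1)
        self.conv2 = nn.Conv1d(c1, c2, config.kernel_size, rng)
        self.bn2 = nn.BatchNorm1d(c2)
        # one trainable classification token per chromosome
        self.register_parameter(
            "token_bank", rng.normal(0.0, 0.02, size=(config.n_chromosomes, c2)))
        self.register_buffer(
            "pos_encoding", nn.sinusoidal_encoding(config.seq_len, c2))
        self.blocks = _BlockList([
            nn.TransformerEncoderBlock(c2, config.n_heads, config.ffn_dim,
                                       config.dropout, rng)
            for _ in range(config.n_transformer_blocks)])
        self.head1 = nn.Linear(c2, c2, rng)
        self.head2 = nn.Linear(c2, config.n_classes, rng)

    # -- stages ---------------------------------------------------------
    def conv_embed(self, signals: Tensor) -> Tensor:
        """(B, window_len) depth signals -> (B, window_len, embed_dim)."""
        B, L = signals.shape
        if L != self.config.window_len:
            raise ValueError(f"signal length {L} != window_len {self.config.window_len}")
        x = signals.reshape(B, 1, L)
        x = nn.relu(self.bn1(self.conv1(x)))
        x = nn.relu(self.bn2(self.conv2(x)))
        return x.transpose(0, 2, 1)  # (B, L, C)

    def assemble_input(self, embedded: Tensor, chromosomes: np.ndarray) -> Tensor:
        """Append the per-chromosome token, then add the positional encoding."""
        B = embedded.shape[0]
        chrom = np.asarray(chromosomes, dtype=np.int64)
        if chrom.shape != (B,):
            raise ValueError("one chromosome id per window required")
        if np.any(chrom < 1) or np.any(chrom > self.config.n_chromosomes):
            raise ValueError(f"chromosome ids must be in 1..{self.config.n_chromosomes}")
        tokens = self.token_bank[chrom - 1].reshape(B, 1, self.config.embed_dim)
        seq = nn.concatenate([embedded, tokens], axis=1)
        return seq + Tensor(self.pos_encoding[None, :, :])

    def forward_batch(self, signals: Tensor, chromosomes: np.ndarray,
                      rng: np.random.Generator | None = None) -> Tensor:
        """Full pass to class probabilities, shape (B, n_classes)."""
        x = self.assemble_input(self.conv_embed(signals), chromosomes)
        for block in self.blocks.items:
            x = block(x, rng)
        token_out = x[:, self.config.window_len, :]
        logits = self.head2(nn.relu(self.head1(token_out)))
        return nn.softmax(logits, axis=-1)

    def forward(self, window: ExonWindow, chromosome: int) -> ForwardTrace:
        """Single-window inference pass recording every stage."""
        was_training = self.training
        self.eval()
        try:
            signals = Tensor(window.signal[None, :])
            embedded = self.conv_embed(signals)
            assembled = self.assemble_input(embedded, np.array([chromosome]))
            x = assembled
            for block in self.blocks.items:
                x = block(x)
            token_out = x.data[0, self.config.window_len, :]
            logits = self.head2(nn.relu(self.head1(
                x[:, self.config.window_len, :])))
            probs = nn.softmax(logits, axis=-1).data[0]
            if not np.all(np.isfinite(x.data)):
                raise FloatingPointError("non-finite activations in transformer output")
            return ForwardTrace(
                embedded=embedded.data[0], assembled=assembled.data[0],
                transformed=x.data[0], token_out=token_out, probabilities=probs)
        finally:
            self.train(was_training)

    def predict_proba(self, signals: np.ndarray, chromosomes: np.ndarray,
                      batch_size: int = 64) -> np.ndarray:
        """Inference-mode class probabilities for (n, window_len) signals."""
        was_training = self.training
        self.eval()
        try:
            outs = []
            for i in range(0, len(signals), batch_size):
                probs = self.forward_batch(Tensor(signals[i:i + batch_size]),
                                           chromosomes[i:i + batch_size])
                outs.append(probs.data)
            return np.concatenate(outs, axis=0)
        finally:
            self.train(was_training)


class _BlockList(nn.Module):
    def __init__(self, items):
        super().__init__()
        self.items = list(items)
        for i, m in enumerate(self.items):
            setattr(self, f"block{i}", m)


def predict_class(trace_or_probs) -> CNVClass:
    """Argmax class; exact probability ties resolve conservatively to NOCALL."""
    probs = getattr(trace_or_probs, "probabilities", trace_or_probs)
    probs = np.asarray(probs)
    best = probs.max()
    winners = np.flatnonzero(probs == best)
    if len(winners) > 1:
        return CNVClass.NOCALL
    return CNVClass(int(winners[0]))


def save_checkpoint(model: CNVTransformer, path: str | Path) -> None:
    """Single-file NPZ archive: config JSON + every weight/buffer array."""
    state = model.state_dict()
    cfg = asdict(model.config)
    cfg["conv_channels"] = list(cfg["conv_channels"])
    np.savez(path,
             __config__=np.frombuffer(
                 json.dumps({"version": CHECKPOINT_VERSION, "config": cfg}).encode(),
                 dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path) -> CNVTransformer:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__config__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = meta["config"]
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        model = CNVTransformer(ModelConfig(**cfg))
        model.load_state_dict({k: npz[k] for k in npz.files if k != "__config__"})
    return model
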