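"""Neural-network layers built on the autograd engine.

Initialization follows common practice (Kaiming-uniform fan-in bounds for
conv/linear weights); every layer draws from the numpy Generator passed to
its constructor so that model construction is fully seed-deterministic.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv1d, relu, softmax

__all__ = [
    "Module", "Linear", "Conv1d", "BatchNorm1d", "LayerNorm", "Dropout",
    "MultiHeadSelfAttention", "TransformerEncoderBlock", "sinusoidal_encoding",
]


class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float64)
        self._buffers[name] = arr
        object.__setattr__(self, name, arr)
        return arr

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for k, v in self._params.items():
            out[prefix + k] = v.data.copy()
        for k, v in self._buffers.items():
            out[prefix + k] = np.asarray(getattr(self, k)).copy()
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for k in self._params:
            self._params[k].data = np.array(state[prefix + k], dtype=np.float64)
        for k in self._buffers:
            arr = np.array(state[prefix + k], dtype=np.float64)
            self._buffers[k] = arr
            object.__setattr__(self, k, arr)
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.register_parameter(
            "weight", _kaiming_uniform(rng, (in_features, out_features), in_features))
        self.register_parameter(
            "bias", _kaiming_uniform(rng, (out_features,), in_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """Same-length convolution, stride 1, odd kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.register_parameter(
            "weight",
            _kaiming_uniform(rng, (out_channels, in_channels, kernel_size), fan_in))
        self.register_parameter("bias", _kaiming_uniform(rng, (out_channels,), fan_in))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias)


class BatchNorm1d(Module):
    """Per-channel normalization over (batch, length) for (B, C, L) input."""

    def __init__(self, num_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.register_parameter("gamma", np.ones(num_channels))
        self.register_parameter("beta", np.zeros(num_channels))
        self.register_buffer("running_mean", np.zeros(num_channels))
        self.register_buffer("running_var", np.ones(num_channels))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2), keepdims=True)
            rm = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            rv = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            self._buffers["running_mean"] = rm
            self._buffers["running_var"] = rv
            object.__setattr__(self, "running_mean", rm)
            object.__setattr__(self, "running_var", rv)
        else:
            mu = Tensor(self.running_mean[None, :, None])
            var = Tensor(self.running_var[None, :, None])
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1) + self.beta.reshape(1, -1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.register_parameter("gamma", np.ones(dim))
        self.register_parameter("beta", np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; the mask RNG is supplied per call for determinism."""

    def __init__(self, p: float):
        super().__init__()
        self.p = float(p)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        if not self.training or self.p <= 0.0 or rng is None:
            return x
        keep = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        H, hd = self.n_heads, self.head_dim

        def split(t: Tensor) -> Tensor:
            return t.reshape(B, T, H, hd).transpose(0, 2, 1, 3)

        q, k, v = split(self.q_proj(x)), split(self.k_proj(x)), split(self.v_proj(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out_proj(ctx)


class TransformerEncoderBlock(Module):
    """Pre-norm encoder block: x + MHSA(LN(x)); x + FFN(LN(x))."""

    def __init__(self, dim: int, n_heads: int, ffn_dim: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ffn1 = Linear(dim, ffn_dim, rng)
        self.ffn2 = Linear(ffn_dim, dim, rng)
        self.drop = Dropout(dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = x + self.drop(self.attn(self.norm1(x)), rng)
        h = self.ffn2(relu(self.ffn1(self.norm2(x))))
        return x + self.drop(h, rng)


def sinusoidal_encoding(length: int, dim: int) -> np.ndarray:
    """Fixed sine/cosine positional encoding, shape (length, dim)."""
    pos = np.arange(length)[:, None].astype(np.float64)
    i = np.arange(dim // 2)[None, :].astype(np.float64)
    angles = pos / np.power(10000.0, 2.0 * i / dim)
    enc = np.zeros((length, dim))
    enc[:, 0::2] = np.sin(angles)
    enc[:, 1::2] = np.cos(angles)
    return enc
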