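"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the CNV classifier needs: broadcasting
arithmetic, batched matmul, reductions, indexing/concatenation, ReLU,
exp/log/sqrt/power, and a fused 1-D convolution. Gradients are accumulated
by topological-order backpropagation from a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "conv1d", "relu", "softmax", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that numpy broadcasting introduced."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      _parents=parents if req else (),
                      _backward=backward if req else None)

    def _accum(self, g: np.ndarray, owned: bool = False) -> None:
        """Accumulate a gradient; `owned=True` promises `g` is a fresh array
        of the right shape/dtype that the caller will not reuse, letting the
        first accumulation adopt it without a copy."""
        if not self.requires_grad:
            return
        if self.grad is None:
            if owned and g.dtype == self.data.dtype and g.shape == self.data.shape:
                self.grad = g
            else:
                self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape), owned=True)
            other._accum(_unbroadcast(g * self.data, other.shape), owned=True)

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g):
            self._accum(g * e * self.data ** (e - 1.0), owned=True)

        return Tensor._make(self.data ** e, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out = np.matmul(self.data, other.data)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            self._accum(_unbroadcast(ga, self.shape), owned=True)
            other._accum(_unbroadcast(gb, other.shape), owned=True)

        return Tensor._make(out, (self, other), backward)

    # -- shape manipulation --------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def backward(g):
            self._accum(np.ascontiguousarray(g).reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy(), owned=True)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims),
                            (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out = np.exp(self.data)

        def backward(g):
            self._accum(g * out, owned=True)

        return Tensor._make(out, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data, owned=True)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- backward pass ----------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask, owned=True)

    return Tensor._make(np.where(mask, x.data, 0.0), (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Fused softmax: d/dx = out * (g - sum(g * out))."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accum(out * (g - dot), owned=True)

    return Tensor._make(out, (x,), backward)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-length 1-D convolution, stride 1, symmetric zero padding.

    x: (B, C_in, L); weight: (C_out, C_in, K) with odd K; bias: (C_out,).
    Output: (B, C_out, L).
    """
    B, C_in, L = x.shape
    C_out, C_in_w, K = weight.shape
    if C_in_w != C_in:
        raise ValueError(f"channel mismatch: input {C_in}, weight {C_in_w}")
    if K % 2 != 1:
        raise ValueError("kernel size must be odd for same-length padding")
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    # im2col view: (B, C_in, K, L)
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, shape=(B, C_in, K, L), strides=(s[0], s[1], s[2], s[2]))
    cols2 = cols.reshape(B, C_in * K, L)
    w2 = weight.data.reshape(C_out, C_in * K)
    out = np.einsum("ok,bkl->bol", w2, cols2, optimize=True)
    out += bias.data[None, :, None]

    def backward(g):
        if weight.requires_grad:
            gw = np.einsum("bol,bkl->ok", g, cols2, optimize=True)
            weight._accum(gw.reshape(C_out, C_in, K))
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.einsum("ok,bol->bkl", w2, g, optimize=True)
            gcols = gcols.reshape(B, C_in, K, L)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k:k + L] += gcols[:, :, k, :]
            x._accum(np.ascontiguousarray(gxp[:, :, pad:pad + L]), owned=True)

    return Tensor._make(out, (x, weight, bias), backward)
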