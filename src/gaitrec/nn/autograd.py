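"""Minimal reverse-mode automatic differentiation on numpy arrays.

The models in this package (recurrent imputer, time-series VAE, denoising
diffusion generator, temporal clustering autoencoder) are small: batches of at
most a few hundred sequences of shape 8x600.  A compact tape-based autodiff
engine over float64 numpy arrays is sufficient and keeps the whole stack
deterministic and dependency-free.

Only the operations those models need are implemented: broadcasting
arithmetic, matmul, elementwise nonlinearities, reductions, reshaping,
slicing, concatenation, and two structured primitives (1-D convolution via
im2col and max-pooling along the time axis) that carry their own backward
rules so the tape stays short.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "conv1d_same", "max_pool_time", "upsample_time"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, slope)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    # -- reductions & shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(self.data[idx], (self,), backward)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = backward
    return out


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 1-D convolution along the middle (time) axis.

    x: (N, T, C_in); w: (K, C_in, C_out); b: (C_out,).  Returns (N, T, C_out).
    Implemented as im2col + matmul so the tape holds a single node.
    """
    N, T, cin = x.data.shape
    K, cin_w, cout = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin} vs kernel {cin_w}")
    pad_l = K // 2
    pad_r = K - 1 - pad_l
    xp = np.pad(x.data, ((0, 0), (pad_l, pad_r), (0, 0)))
    # cols: (N, T, K*cin)
    cols = np.empty((N, T, K * cin))
    for k in range(K):
        cols[:, :, k * cin : (k + 1) * cin] = xp[:, k : k + T, :]
    w2 = w.data.reshape(K * cin, cout)
    out_data = cols.reshape(N * T, K * cin) @ w2 + b.data
    out = Tensor(out_data.reshape(N, T, cout))
    out.requires_grad = x.requires_grad or w.requires_grad or b.requires_grad
    if out.requires_grad:
        out._parents = (x, w, b)

        def backward(g):
            g2 = g.reshape(N * T, cout)
            if b.requires_grad:
                b._accum(g2.sum(axis=0))
            if w.requires_grad:
                gw = cols.reshape(N * T, K * cin).T @ g2
                w._accum(gw.reshape(K, cin, cout))
            if x.requires_grad:
                gcols = (g2 @ w2.T).reshape(N, T, K, cin)
                gxp = np.zeros_like(xp)
                for k in range(K):
                    gxp[:, k : k + T, :] += gcols[:, :, k, :]
                x._accum(gxp[:, pad_l : pad_l + T, :])

        out._backward = backward
    return out


def max_pool_time(x: Tensor, pool: int) -> Tensor:
    """Max-pool along the time axis with right-padding by -inf.

    x: (N, T, C) -> (N, ceil(T / pool), C).
    """
    N, T, C = x.data.shape
    T_out = -(-T // pool)
    pad = T_out * pool - T
    xp = np.pad(x.data, ((0, 0), (0, pad), (0, 0)), constant_values=-np.inf)
    blocks = xp.reshape(N, T_out, pool, C)
    arg = blocks.argmax(axis=2)  # (N, T_out, C)
    out = Tensor(np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :])
    out.requires_grad = x.requires_grad
    if out.requires_grad:
        out._parents = (x,)

        def backward(g):
            gblocks = np.zeros_like(blocks)
            np.put_along_axis(gblocks, arg[:, :, None, :], g[:, :, None, :], axis=2)
            x._accum(gblocks.reshape(N, T_out * pool, C)[:, :T, :])

        out._backward = backward
    return out


def upsample_time(x: Tensor, factor: int, target_len: int) -> Tensor:
    """Nearest-neighbour upsampling along time, cropped to `target_len`."""
    N, T, C = x.data.shape
    rep = np.repeat(x.data, factor, axis=1)[:, :target_len, :]
    out = Tensor(rep)
    out.requires_grad = x.requires_grad
    if out.requires_grad:
        out._parents = (x,)

        def backward(g):
            gfull = np.zeros((N, T * factor, C))
            gfull[:, :target_len, :] = g
            x._accum(gfull.reshape(N, T, factor, C).sum(axis=2))

        out._backward = backward
    return out
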