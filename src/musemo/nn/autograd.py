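"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery to express and train the 1-D CNN / self-attention /
BiLSTM classifier in this package: a :class:`Tensor` wrapping a float64
array, elementwise and matmul primitives with broadcasting-aware
backward rules, and structural ops (reshape, transpose, concat, slice).
Layer-level primitives with bespoke backward passes (convolution, pooling,
batch norm, cross-entropy) live here too because their gradients are
cheaper hand-written than composed.

Everything is float64 and single-threaded NumPy, so runs are bitwise
reproducible for a fixed seed.  All primitives are finite-difference
checked in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv1d", "max_pool1d", "avg_pool1d",
           "batch_norm", "softmax", "cross_entropy_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A float64 ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad}{tag})"

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        """Reverse-accumulate gradients from this tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._from_op(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- nonlinearities ----------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._from_op(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    # -- reductions ------------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy()
                            if np.ndim(g) else np.full_like(self.data, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- structure -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._from_op(out_data, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._from_op(out_data, (self,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# layer-level primitives with hand-written gradients
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kernel: int, stride: int, padding: int):
    """(N, C, L) -> column tensor (N, L_out, C*kernel) plus the gather index."""
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
    n, c, L = x.shape
    l_out = (L - kernel) // stride + 1
    idx = stride * np.arange(l_out)[:, None] + np.arange(kernel)[None, :]
    cols = x[:, :, idx]                      # (N, C, L_out, K)
    cols = cols.transpose(0, 2, 1, 3).reshape(n, l_out, c * kernel)
    return cols, idx, x.shape


def conv1d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1,
           padding: int = 0) -> Tensor:
    """1-D convolution (cross-correlation): x (N,C,L), weight (F,C,K) ->
    (N,F,L_out) with L_out = floor((L + 2p - K)/stride) + 1."""
    n, c, L = x.data.shape
    f, c_w, k = weight.data.shape
    if c != c_w:
        raise ValueError(f"channel mismatch: input {c}, weight {c_w}")
    l_out = (L + 2 * padding - k) // stride + 1
    if l_out < 1:
        raise ValueError("convolution output length < 1")
    cols, idx, padded_shape = _im2col(x.data, k, stride, padding)
    w2 = weight.data.reshape(f, c * k)
    out_data = cols @ w2.T + bias.data[None, None, :]   # (N, L_out, F)
    out_data = out_data.transpose(0, 2, 1)

    def backward(g):
        gt = g.transpose(0, 2, 1)                        # (N, L_out, F)
        if bias.requires_grad:
            bias._accum(gt.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.einsum("nlf,nlk->fk", gt, cols)
            weight._accum(gw.reshape(f, c, k))
        if x.requires_grad:
            gcols = gt @ w2                               # (N, L_out, C*K)
            gcols = gcols.reshape(n, l_out, c, k).transpose(0, 2, 1, 3)
            gx = np.zeros(padded_shape)
            np.add.at(gx, (slice(None), slice(None), idx), gcols)
            if padding:
                gx = gx[:, :, padding:-padding]
            x._accum(gx)

    return Tensor._from_op(out_data, (x, weight, bias), backward)


def _pool_windows(x: np.ndarray, size: int, stride: int):
    n, c, L = x.shape
    l_out = (L - size) // stride + 1
    idx = stride * np.arange(l_out)[:, None] + np.arange(size)[None, :]
    return x[:, :, idx], idx, l_out      # (N, C, L_out, size)


def max_pool1d(x: Tensor, size: int, stride: int | None = None) -> Tensor:
    stride = size if stride is None else stride
    win, idx, l_out = _pool_windows(x.data, size, stride)
    arg = win.argmax(axis=3)
    out_data = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        n, c, _ = x.data.shape
        pos = stride * np.arange(l_out)[None, None, :] + arg
        np.add.at(
            gx,
            (np.arange(n)[:, None, None], np.arange(c)[None, :, None], pos),
            g,
        )
        x._accum(gx)

    return Tensor._from_op(out_data, (x,), backward)


def avg_pool1d(x: Tensor, size: int, stride: int | None = None) -> Tensor:
    stride = size if stride is None else stride
    win, idx, l_out = _pool_windows(x.data, size, stride)
    out_data = win.mean(axis=3)

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), idx), g[..., None] / size)
        x._accum(gx)

    return Tensor._from_op(out_data, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5,
               running: dict | None = None, momentum: float = 0.1,
               training: bool = True) -> Tensor:
    """Batch normalization over (N, L) for each channel of (N, C, L).

    ``running`` holds running mean/var used at inference; updated in place
    during training.
    """
    nd = x.data
    axes = (0, 2)
    if training:
        mean = nd.mean(axis=axes)
        var = nd.var(axis=axes)
        if running is not None:
            running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
            running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean = running["mean"]
        var = running["var"]
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (nd - mean[None, :, None]) * inv_std[None, :, None]
    out_data = gamma.data[None, :, None] * xhat + beta.data[None, :, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gsc = g * gamma.data[None, :, None]
            if training:
                m = nd.shape[0] * nd.shape[2]
                s1 = gsc.sum(axis=axes)
                s2 = (gsc * xhat).sum(axis=axes)
                gx = (inv_std[None, :, None] / m) * (
                    m * gsc - s1[None, :, None] - xhat * s2[None, :, None]
                )
            else:
                gx = gsc * inv_std[None, :, None]
            x._accum(gx)

    return Tensor._from_op(out_data, (x, gamma, beta), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``."""
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            x._accum(out_data * (g - dot))

    return Tensor._from_op(out_data, (x,), backward)


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw logits (N, K)."""
    labels = np.asarray(labels, dtype=np.intp)
    n = logits.data.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - lse
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        if logits.requires_grad:
            probs = np.exp(logp)
            probs[np.arange(n), labels] -= 1.0
            logits._accum(g * probs / n)

    return Tensor._from_op(loss, (logits,), backward)
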