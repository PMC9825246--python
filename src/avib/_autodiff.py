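"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the variational encoder–decoder needs:
broadcast-aware arithmetic, (batched) matmul, exp/log/tanh/relu, stable
sigmoid/softplus/softmax, axis reductions (sum/mean/max), shape ops, 1-D
convolution, and clipping. Everything is float64; gradients are accumulated
by topological-order backpropagation from a scalar loss.

The public model API never exposes these objects — they are internal to the
training loop, the attention aggregator and the ODIN input-gradient step.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "conv1d"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray <op> Tensor dispatches here

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ---- graph plumbing -------------------------------------------------

    @staticmethod
    def _make(value, parents, backward) -> "Tensor":
        out = Tensor(value)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.value)
        # topological order by DFS
        topo, seen = [], set()
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- basics ---------------------------------------------------------

    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def __repr__(self):
        return f"Tensor(shape={self.value.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.value)

    # ---- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.value + other.value, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.value.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.value, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.value * other.value, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.value, self.value.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.value, other.value.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.value / other.value, (self, other), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.value, self.value.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.value / other.value**2, other.value.shape)
                )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor._make(self.value**exponent, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.value ** (exponent - 1))

        out._backward = backward
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.value @ other.value, (self, other), None)

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.value, -1, -2)
                self._accumulate(_unbroadcast(ga, self.value.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.value, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.value.shape))

        out._backward = backward
        return out

    # ---- elementwise functions ------------------------------------------

    def exp(self):
        val = np.exp(self.value)
        out = Tensor._make(val, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = backward
        return out

    def log(self):
        out = Tensor._make(np.log(self.value), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.value)

        out._backward = backward
        return out

    def tanh(self):
        val = np.tanh(self.value)
        out = Tensor._make(val, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - val**2))

        out._backward = backward
        return out

    def relu(self):
        mask = self.value > 0
        out = Tensor._make(np.where(mask, self.value, 0.0), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = backward
        return out

    def sigmoid(self):
        # numerically stable for large |x|
        val = np.where(
            self.value >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.value))),
            np.exp(-np.abs(self.value)) / (1.0 + np.exp(-np.abs(self.value))),
        )
        out = Tensor._make(val, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * val * (1.0 - val))

        out._backward = backward
        return out

    def softplus(self):
        # log(1 + e^x) = max(x, 0) + log1p(e^{-|x|})
        val = np.maximum(self.value, 0.0) + np.log1p(np.exp(-np.abs(self.value)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.value, -500, 500)))
        out = Tensor._make(val, (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * sig)

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float):
        """Clip values; gradient passes only where lo < value < hi."""
        mask = (self.value > lo) & (self.value < hi)
        out = Tensor._make(np.clip(self.value, lo, hi), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = backward
        return out

    # ---- reductions -----------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.value.sum(axis=axis, keepdims=keepdims), (self,), None)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.value.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.value.shape))

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Max along one axis; ties route the gradient to the first index."""
        idx = np.argmax(self.value, axis=axis)
        val = np.take_along_axis(self.value, np.expand_dims(idx, axis), axis=axis)
        out_val = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor._make(out_val, (self,), None)

        def backward(g):
            if not self.requires_grad:
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            full = np.zeros_like(self.value)
            np.put_along_axis(full, np.expand_dims(idx, axis), gg, axis=axis)
            self._accumulate(full)

        out._backward = backward
        return out

    def softmax(self, axis: int = -1):
        """Row-stochastic softmax; shift-invariance makes the detached
        max-shift below exactly gradient-correct."""
        shifted = self.value - self.value.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        val = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(val, (self,), None)

        def backward(g):
            if self.requires_grad:
                dot = (g * val).sum(axis=axis, keepdims=True)
                self._accumulate(val * (g - dot))

        out._backward = backward
        return out

    # ---- shape ops -------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._make(self.value.reshape(shape), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.value.shape))

        out._backward = backward
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor._make(self.value.transpose(axes), (self,), None)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = backward
        return out

    def __getitem__(self, key):
        out = Tensor._make(self.value[key], (self,), None)

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.value)
                np.add.at(full, key, g)
                self._accumulate(full)

        out._backward = backward
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    val = np.concatenate([t.value for t in tensors], axis=axis)
    out = Tensor._make(val, tuple(tensors), None)
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor, pad: int = 1) -> Tensor:
    """1-D convolution with zero padding.

    x: (B, C_in, N), w: (C_out, C_in, k), b: (C_out,) -> (B, C_out, N_out)
    with N_out = N + 2*pad - k + 1.
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    B, cin, n = x.value.shape
    cout, cin_w, k = w.value.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(x.value, ((0, 0), (0, 0), (pad, pad)))
    n_out = n + 2 * pad - k + 1
    if n_out < 1:
        raise ValueError(f"sequence too short for kernel {k} with pad {pad}")
    # im2col: (B, n_out, cin*k)
    idx = np.arange(k)[None, :] + np.arange(n_out)[:, None]  # (n_out, k)
    cols = xp[:, :, idx]                   # (B, cin, n_out, k)
    cols = cols.transpose(0, 2, 1, 3).reshape(B, n_out, cin * k)
    wmat = w.value.reshape(cout, cin * k)  # (cout, cin*k)
    val = cols @ wmat.T + b.value[None, None, :]        # (B, n_out, cout)
    val = val.transpose(0, 2, 1)                        # (B, cout, n_out)
    out = Tensor._make(val, (x, w, b), None)

    def backward(g):
        gt = g.transpose(0, 2, 1)                       # (B, n_out, cout)
        if b.requires_grad:
            b._accumulate(gt.sum(axis=(0, 1)))
        if w.requires_grad:
            gw = np.einsum("bnc,bnf->cf", gt, cols)     # (cout, cin*k)
            w._accumulate(gw.reshape(cout, cin, k))
        if x.requires_grad:
            gcols = gt @ wmat                           # (B, n_out, cin*k)
            gcols = gcols.reshape(B, n_out, cin, k).transpose(0, 2, 1, 3)
            gxp = np.zeros_like(xp)
            np.add.at(gxp, (slice(None), slice(None), idx), gcols)
            x._accumulate(gxp[:, :, pad : pad + n] if pad else gxp)

    out._backward = backward
    return out
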