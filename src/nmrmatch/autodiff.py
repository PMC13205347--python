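"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  The op set is exactly what the molecule--spectrum
matching network needs: broadcasted arithmetic, matmul, elementwise
nonlinearities, axis reductions, reshaping/concatenation, row gather /
segment reductions for graph message passing, and 2-D convolution.

Everything is float64-agnostic: arrays keep whatever dtype they are given
(float32 throughout the model for memory; tests often use float64 for tight
oracle comparisons).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "gather_rows", "segment_sum",
           "segment_max", "conv2d", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph recording (evaluation-mode forward)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (many layers/steps)
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other, like=self)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.data.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other, like=self))

    def __rsub__(self, other):
        return as_tensor(other, like=self) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, like=self)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.data.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, like=self)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(
                        -g * self.data / (other.data ** 2), other.data.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other, like=self) / self

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other, like=self)
        out = _make(self.data @ other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accumulate(g @ np.swapaxes(other.data, -1, -2))
                if other.requires_grad:
                    other._accumulate(np.swapaxes(self.data, -1, -2) @ g)
            out._backward = bw
        return out

    # ------------------------------------------------------------ elementwise
    def exp(self):
        val = np.exp(self.data)
        out = _make(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * val)
        return out

    def log(self):
        out = _make(np.log(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = _make(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * 0.5 / val)
        return out

    def relu(self):
        mask = self.data > 0
        out = _make(self.data * mask, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def sigmoid(self):
        with np.errstate(over="ignore"):    # exp overflow saturates to 0/1
            val = 1.0 / (1.0 + np.exp(-self.data))
        out = _make(val, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * val * (1.0 - val))
        return out

    def clip_min(self, lo: float):
        """max(x, lo); gradient passes where x > lo."""
        mask = self.data > lo
        out = _make(np.maximum(self.data, lo), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    # -------------------------------------------------------------- reduction
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.data.shape))
                    return
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        val = self.data.max(axis=axis, keepdims=True)
        out_val = val if keepdims else np.squeeze(val, axis=axis)
        out = _make(out_val, (self,))
        if out.requires_grad:
            # route the gradient to the (first) argmax along `axis`
            mask = self.data == val
            first = np.cumsum(mask, axis=axis) == 1
            mask = mask & first
            def bw(g):
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(mask * gg)
            out._backward = bw
        return out

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(
                g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        out = _make(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = bw
        return out


def _make(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
    return out


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))


# ---------------------------------------------------------------- free functions

def concat(tensors: list, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = bw
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """``t[idx]`` along axis 0 with scatter-add backward."""
    idx = np.asarray(idx)
    out = _make(t.data[idx], (t,))
    if out.requires_grad:
        def bw(g):
            full = np.zeros_like(t.data)
            np.add.at(full, idx, g)
            t._accumulate(full)
        out._backward = bw
    return out


def segment_sum(t: Tensor, seg_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given per-row ids."""
    seg_ids = np.asarray(seg_ids)
    val = np.zeros((num_segments,) + t.data.shape[1:], dtype=t.data.dtype)
    np.add.at(val, seg_ids, t.data)
    out = _make(val, (t,))
    if out.requires_grad:
        out._backward = lambda g: t._accumulate(g[seg_ids])
    return out


def segment_max(t: Tensor, seg_ids: np.ndarray, num_segments: int) -> Tensor:
    """Per-segment elementwise max over rows (every segment must be nonempty)."""
    seg_ids = np.asarray(seg_ids)
    val = np.full((num_segments,) + t.data.shape[1:], -np.inf, dtype=t.data.dtype)
    np.maximum.at(val, seg_ids, t.data)
    out = _make(val, (t,))
    if out.requires_grad:
        mask = (t.data == val[seg_ids]).astype(t.data.dtype)
        # ties split the gradient evenly among attaining rows
        n_attain = np.zeros_like(val)
        np.add.at(n_attain, seg_ids, mask)
        def bw(g):
            t._accumulate(mask * (g / n_attain)[seg_ids])
        out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, square stride/padding, via im2col.

    x: (N, C, H, W); w: (O, C, kh, kw); b: (O,) or None.
    """
    N, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Cw}")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho = (xp.shape[2] - kh) // stride + 1
    Wo = (xp.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                  # (N,C,Ho,Wo,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * kh * kw)
    wf = w.data.reshape(O, -1)
    out_data = cols @ wf.T
    if b is not None:
        out_data = out_data + b.data
    out_data = out_data.reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = _make(np.ascontiguousarray(out_data), parents)
    if out.requires_grad:
        def bw(g):
            gf = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, O)
            if b is not None and b.requires_grad:
                b._accumulate(gf.sum(axis=0))
            if w.requires_grad:
                w._accumulate((gf.T @ cols).reshape(w.data.shape))
            if x.requires_grad:
                dcols = (gf @ wf).reshape(N, Ho, Wo, C, kh, kw)
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + Ho * stride:stride,
                            j:j + Wo * stride:stride] += \
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                x._accumulate(dxp)
        out._backward = bw
    return out
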