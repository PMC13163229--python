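"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's network blocks, trainer and Grad-CAM all run on this engine.
Tensors form a DAG; :meth:`Tensor.backward` topologically sorts the graph and
accumulates gradients into ``.grad``. Only the operations the dual-stream
architecture needs are provided (dense algebra, 2-D convolutions, pooling,
reductions, elementwise nonlinearities). Data layout for images is NHWC.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "log",
    "pow_const",
    "reduce_mean",
    "reduce_max",
    "concat",
    "reshape",
    "conv2d",
    "depthwise_conv2d",
    "maxpool2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, _parents=(), name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = _parents
        self.name = name

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
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
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), Tensor(-1.0)))

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def reshape(self, *shape):
        return reshape(self, shape)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req, _parents=tuple(p for p in parents if p.requires_grad))
    if req:
        out._backward = backward
    return out


# -- elementwise ----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    data = np.maximum(x.data, 0.0)

    def backward(g):
        x._accumulate(g * (x.data > 0.0))

    return _make(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    from scipy.special import expit

    data = expit(x.data)

    def backward(g):
        x._accumulate(g * data * (1.0 - data))

    return _make(data, (x,), backward)


def log(x: Tensor) -> Tensor:
    data = np.log(x.data)

    def backward(g):
        x._accumulate(g / x.data)

    return _make(data, (x,), backward)


def pow_const(x: Tensor, p: float) -> Tensor:
    data = np.power(x.data, p)

    def backward(g):
        x._accumulate(g * p * np.power(x.data, p - 1.0))

    return _make(data, (x,), backward)


# -- reductions / shape ----------------------------------------------------

def reduce_mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = x.data.mean(axis=axis, keepdims=keepdims)
    n = x.data.size / data.size

    def backward(g):
        g = np.asarray(g)
        if not keepdims and axis is not None:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape) / n)

    return _make(data, (x,), backward)


def reduce_max(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max over one axis; ties route the gradient to the first maximum."""
    data = x.data.max(axis=axis, keepdims=keepdims)
    idx = np.argmax(x.data, axis=axis, keepdims=True)

    def backward(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, np.take_along_axis(gx, idx, axis) + g, axis)
        x._accumulate(gx)

    return _make(data, (x,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def reshape(x: Tensor, shape) -> Tensor:
    data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return _make(data, (x,), backward)


# -- convolutions ----------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, pad_value: float = 0.0):
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)), constant_values=pad_value)
    n, h, w, c = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (n, ho, wo, c, kh, kw)
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * ho * wo, kh * kw * c)
    return cols, ho, wo


def _col2im(cols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int, ho: int, wo: int):
    n, h, w, c = xshape
    xp = np.zeros((n, h + 2 * pad, w + 2 * pad, c))
    cols = cols.reshape(n, ho, wo, kh, kw, c)
    for i in range(kh):
        for j in range(kw):
            xp[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :] += cols[:, :, :, i, j, :]
    return xp[:, pad : h + pad, pad : w + pad, :]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, padding: int | str = "same") -> Tensor:
    """2-D convolution; ``w`` has shape (kh, kw, Cin, Cout), layout NHWC.

    ``padding='same'`` (odd kernels, stride 1) or an explicit symmetric pad.
    """
    kh, kw, cin, cout = w.data.shape
    if x.data.ndim != 4:
        raise ValueError(f"conv2d expects NHWC input, got shape {x.data.shape}")
    if x.data.shape[3] != cin:
        raise ValueError(f"conv2d channel mismatch: input has {x.data.shape[3]}, kernel expects {cin}")
    if padding == "same":
        if stride != 1:
            raise ValueError("padding='same' supported only for stride 1")
        pad = (kh - 1) // 2
    else:
        pad = int(padding)
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(kh * kw * cin, cout)
    out = cols @ wmat
    if b is not None:
        out = out + b.data
    n = x.data.shape[0]
    data = out.reshape(n, ho, wo, cout)

    def backward(g):
        gmat = g.reshape(n * ho * wo, cout)
        if w.requires_grad:
            w._accumulate((cols.T @ gmat).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = gmat @ wmat.T
            x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, pad, ho, wo))

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Depthwise 3x3-style convolution (depth multiplier 1), stride 1, same padding.

    ``w`` has shape (kh, kw, C).
    """
    kh, kw, c = w.data.shape
    if x.data.shape[3] != c:
        raise ValueError(f"depthwise channel mismatch: input has {x.data.shape[3]}, kernel expects {c}")
    pad = (kh - 1) // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    n, h, wdt, _ = x.data.shape
    out = np.zeros_like(x.data)
    for i in range(kh):
        for j in range(kw):
            out += xp[:, i : i + h, j : j + wdt, :] * w.data[i, j, :]
    if b is not None:
        out = out + b.data
    data = out

    def backward(g):
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[i, j, :] = (xp[:, i : i + h, j : j + wdt, :] * g).sum(axis=(0, 1, 2))
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i : i + h, j : j + wdt, :] += g * w.data[i, j, :]
            x._accumulate(gxp[:, pad : h + pad, pad : wdt + pad, :])

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


def maxpool2d(x: Tensor, pool: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling with symmetric padding (padded cells never win: -inf fill)."""
    n, h, w, c = x.data.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (padding, padding), (padding, padding), (0, 0)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (pool, pool), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (n, ho, wo, c, ph, pw)
    ho, wo = win.shape[1], win.shape[2]
    flat = win.reshape(n, ho, wo, c, pool * pool)
    idx = flat.argmax(axis=4)
    data = np.take_along_axis(flat, idx[..., None], axis=4)[..., 0]

    def backward(g):
        gxp = np.zeros((n, h + 2 * padding, w + 2 * padding, c))
        for k in range(pool * pool):
            i, j = divmod(k, pool)
            mask = idx == k
            if not mask.any():
                continue
            sub = gxp[:, i : i + ho * stride : stride, j : j + wo * stride : stride, :]
            sub += g * mask
        x._accumulate(gxp[:, padding : h + padding, padding : w + padding, :])

    return _make(data, (x,), backward)
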