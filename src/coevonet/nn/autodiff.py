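"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package needs gradients to flow from a contact-map loss back through a
residual CNN, the covariance-feature computation, and a sequence-weighting
MLP.  No autodiff framework is assumed to be installed, so this module
implements a small tape-based engine: a :class:`Tensor` wraps an ndarray,
records its parents and a backward closure, and ``backward()`` walks the
tape in reverse topological order.

Only the operations the models use are provided (broadcast arithmetic,
matmul, elementwise nonlinearities, reductions, reshaping, indexing, 2-D
convolution).  Dtype follows the data: float32 for training speed, float64
where tests compare against finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "log",
    "exp",
    "sqrt",
    "clip",
    "relu",
    "sigmoid",
    "softplus",
    "softmax",
    "concat",
    "broadcast_to",
    "conv2d",
]


def _as_array(x, dtype=None):
    a = np.asarray(x, dtype=dtype)
    if a.dtype.kind in "iub":
        a = a.astype(np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    nextra = grad.ndim - len(shape)
    if nextra > 0:
        grad = grad.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make `ndarray <op> Tensor` defer to the reflected Tensor ops
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def T(self):
        return self.transpose()

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def detach(self):
        return Tensor(self.data)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (60-layer trunks)
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _ensure(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-_ensure(other))

    def __rsub__(self, other):
        return _ensure(other) + (-self)

    def __mul__(self, other):
        other = _ensure(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _ensure(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return _ensure(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = back
        return out

    def __matmul__(self, other):
        other = _ensure(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def back(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = back
        return out

    def __rmatmul__(self, other):
        return _ensure(other) @ self

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))
        axes = _norm_axes(axis, self.data.ndim)

        def back(g):
            if not self.requires_grad:
                return
            if axes is not None and not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in _norm_axes(axis, self.data.ndim)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # ------------------------------------------------------------------ shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _parents=(self,))

        def back(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = back
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(range(self.data.ndim))[::-1]
        out = Tensor(np.transpose(self.data, axes), _parents=(self,))
        inv = np.argsort(axes)

        def back(g):
            if self.requires_grad:
                self._accumulate(np.transpose(g, inv))

        out._backward = back
        return out

    def __getitem__(self, index):
        out = Tensor(self.data[index], _parents=(self,))

        def back(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, index, g)
                self._accumulate(gx)

        out._backward = back
        return out


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _norm_axes(axis, ndim):
    if axis is None:
        return None
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def tensor(data, requires_grad=False):
    return Tensor(data, requires_grad=requires_grad)


# --------------------------------------------------------------------- unary
# Each function dispatches: Tensor in -> Tensor out, ndarray in -> ndarray
# out, so feature code can be written once and reused on both paths.


def log(x):
    if not isinstance(x, Tensor):
        return np.log(x)
    out = Tensor(np.log(x.data), _parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    out._backward = back
    return out


def exp(x):
    if not isinstance(x, Tensor):
        return np.exp(x)
    out = Tensor(np.exp(x.data), _parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * out.data)

    out._backward = back
    return out


def sqrt(x):
    if not isinstance(x, Tensor):
        return np.sqrt(x)
    out = Tensor(np.sqrt(x.data), _parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * 0.5 / out.data)

    out._backward = back
    return out


def clip(x, lo, hi):
    """Clamp values; gradient passes through the un-clipped region only."""
    if not isinstance(x, Tensor):
        return np.clip(x, lo, hi)
    out = Tensor(np.clip(x.data, lo, hi), _parents=(x,))
    mask = (x.data >= lo) & (x.data <= hi)

    def back(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = back
    return out


def relu(x):
    if not isinstance(x, Tensor):
        return np.maximum(x, 0)
    out = Tensor(np.maximum(x.data, 0), _parents=(x,))
    mask = x.data > 0

    def back(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = back
    return out


def sigmoid(x):
    if not isinstance(x, Tensor):
        return 1.0 / (1.0 + np.exp(-x))
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = back
    return out


def softplus(x):
    if not isinstance(x, Tensor):
        return np.logaddexp(0.0, x)
    out = Tensor(np.logaddexp(0.0, x.data), _parents=(x,))
    s = 1.0 / (1.0 + np.exp(-x.data))

    def back(g):
        if x.requires_grad:
            x._accumulate(g * s)

    out._backward = back
    return out


def softmax(x, axis=-1):
    if not isinstance(x, Tensor):
        z = x - np.max(x, axis=axis, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=axis, keepdims=True)
    z = x.data - np.max(x.data, axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(x,))

    def back(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accumulate(y * (g - dot))

    out._backward = back
    return out


# ------------------------------------------------------------------- shaping


def concat(parts, axis=0):
    if not any(isinstance(p, Tensor) for p in parts):
        return np.concatenate(parts, axis=axis)
    parts = [_ensure(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), _parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for p, a, b in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                p._accumulate(g[tuple(idx)])

    out._backward = back
    return out


def broadcast_to(x, shape):
    if not isinstance(x, Tensor):
        return np.broadcast_to(x, shape)
    out = Tensor(np.broadcast_to(x.data, shape).copy(), _parents=(x,))

    def back(g):
        if x.requires_grad:
            x._accumulate(_unbroadcast(g, x.data.shape))

    out._backward = back
    return out


# --------------------------------------------------------------- convolution


def conv2d(x: Tensor, weight: Tensor, bias: Tensor):
    """'Same'-padded 2-D convolution of one image.

    x: (C_in, H, W); weight: (C_out, C_in, kh, kw) with odd kh == kw;
    bias: (C_out,).  Implemented as kh*kw shifted matmuls, which is fast in
    numpy for the small kernels used here (1x1 and 3x3).
    """
    x, weight, bias = _ensure(x), _ensure(weight), _ensure(bias)
    cin, H, W = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
    out_data = np.zeros((cout, H, W), dtype=x.data.dtype)
    flat = out_data.reshape(cout, H * W)
    for dy in range(kh):
        for dx in range(kw):
            patch = xp[:, dy : dy + H, dx : dx + W].reshape(cin, H * W)
            flat += weight.data[:, :, dy, dx] @ patch
    out_data += bias.data[:, None, None]
    out = Tensor(out_data, _parents=(x, weight, bias))

    def back(g):
        g2 = g.reshape(cout, H * W)
        if bias.requires_grad:
            bias._accumulate(g.sum(axis=(1, 2)))
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for dy in range(kh):
                for dx in range(kw):
                    patch = xp[:, dy : dy + H, dx : dx + W].reshape(cin, H * W)
                    gw[:, :, dy, dx] = g2 @ patch.T
            weight._accumulate(gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for dy in range(kh):
                for dx in range(kw):
                    gxp[:, dy : dy + H, dx : dx + W] += (
                        weight.data[:, :, dy, dx].T @ g2
                    ).reshape(cin, H, W)
            x._accumulate(gxp[:, ph : ph + H, pw : pw + W])

    out._backward = back
    return out
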