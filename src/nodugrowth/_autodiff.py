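"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the growth-prediction network needs:
elementwise arithmetic, exp/log and the sigmoid/softplus/relu
nonlinearities, reductions, channel concatenation, 3x3 "same"
convolution via im2col, 2x2 average pooling and nearest-neighbour
upsampling.  Tensors are NCHW (or any broadcastable shape for scalar
conditioning values).  Gradients are accumulated by a topological sweep
over the recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "avg_pool2d", "upsample2x", "Adam", "no_grad"]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph recording (inference-time forwards)."""

    def __enter__(self):
        _GRAD_ENABLED.append(False)

    def __exit__(self, *exc):
        _GRAD_ENABLED.pop()
        return False


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float64, copy=False)
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): _as_array(grad)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg

    # -- basic ops -----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        sa, sb = self.data.shape, other.data.shape
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, sa), _unbroadcast(g, sb)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        sa, sb = self.data.shape, other.data.shape
        a, b = self.data, other.data
        return Tensor._make(
            a * b,
            (self, other),
            lambda g: (_unbroadcast(g * b, sa), _unbroadcast(g * a, sb)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, k: float):
        a = self.data
        return Tensor._make(a ** k, (self,), lambda g: (g * k * a ** (k - 1),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        a = self.data
        return Tensor._make(np.log(a), (self,), lambda g: (g / a,))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self.data
        out = np.where(a >= 0, 1.0 / (1.0 + np.exp(-np.abs(a))),
                       np.exp(-np.abs(a)) / (1.0 + np.exp(-np.abs(a))))
        return Tensor._make(out, (self,), lambda g: (g * out * (1 - out),))

    def softplus(self):
        a = self.data
        out = np.logaddexp(0.0, a)
        sig = np.where(a >= 0, 1.0 / (1.0 + np.exp(-np.abs(a))),
                       np.exp(-np.abs(a)) / (1.0 + np.exp(-np.abs(a))))
        return Tensor._make(out, (self,), lambda g: (g * sig,))

    def sum(self, axis=None, keepdims=False):
        a_shape = self.data.shape
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, a_shape).copy(),)
            gg = g
            if not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                for ax in sorted(a % len(a_shape) for a in axes):
                    gg = np.expand_dims(gg, ax)
            return (np.broadcast_to(gg, a_shape).copy(),)

        return Tensor._make(out, (self,), back)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, int):
            n = self.data.shape[axis]
        else:
            n = int(np.prod([self.data.shape[a] for a in axis]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Maximum along one axis; gradient routed to the (first) argmax."""
        out = self.data.max(axis=axis)
        hot = self.data == np.expand_dims(out, axis)
        # break ties toward the first maximum
        first = np.cumsum(hot, axis=axis) == 1
        hot = hot & first

        def back(g):
            return (np.expand_dims(g, axis) * hot,)

        return Tensor._make(out, (self,), back)

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def matmul(self, other: "Tensor"):
        a, b = self.data, other.data
        return Tensor._make(
            a @ b,
            (self, other),
            lambda g: (g @ b.swapaxes(-1, -2), a.swapaxes(-1, -2) @ g),
        )

    def item(self) -> float:
        return float(self.data)


def slice_channels(x: Tensor, start: int, stop: int) -> Tensor:
    """Slice along axis 1 (channels)."""
    shape = x.data.shape

    def back(g):
        full = np.zeros(shape)
        full[:, start:stop] = g
        return (full,)

    return Tensor._make(x.data[:, start:stop], (x,), back)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), back)


# -- convolution -------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """x: (N,C,H,W) zero-padded 'same' -> (N, H*W, C*kh*kw)."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> (N, H*W, C*kh*kw)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * kh * kw)


def _col2im(cols: np.ndarray, shape: tuple, kh: int, kw: int) -> np.ndarray:
    """Adjoint of _im2col."""
    n, c, h, w = shape
    ph, pw = kh // 2, kw // 2
    cols = cols.reshape(n, h, w, c, kh, kw)
    xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return xp[:, :, ph : ph + h, pw : pw + w]


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """'same' convolution, stride 1.  w: (F, C, kh, kw), b: (F,)."""
    n, c, h, wd = x.data.shape
    f, _, kh, kw = w.data.shape
    cols = _im2col(x.data, kh, kw)  # (N, HW, Ckk)
    wmat = w.data.reshape(f, -1)  # (F, Ckk)
    out = cols @ wmat.T + b.data  # (N, HW, F)
    out = out.transpose(0, 2, 1).reshape(n, f, h, wd)

    def back(g):
        gm = g.reshape(n, f, h * wd).transpose(0, 2, 1)  # (N, HW, F)
        dcols = gm @ wmat  # (N, HW, Ckk)
        dx = _col2im(dcols, x.data.shape, kh, kw)
        dw = (
            gm.reshape(-1, f).T @ cols.reshape(-1, cols.shape[-1])
        ).reshape(w.data.shape)
        db = gm.sum(axis=(0, 1))
        return dx, dw, db

    return Tensor._make(out, (x, w, b), back)


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2."""
    n, c, h, w = x.data.shape
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def back(g):
        return (np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0,)

    return Tensor._make(out, (x,), back)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling."""
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    n, c, h, w = x.data.shape

    def back(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return Tensor._make(out, (x,), back)


class Adam:
    """Adam optimizer over a list of leaf Tensors."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
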