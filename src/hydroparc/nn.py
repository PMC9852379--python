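"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a compact engine sized for the small convolutional networks used by
:mod:`hydroparc.inpainting` (a partial-convolution U-Net generator, an
encoder discriminator and a fixed feature extractor).  It supports exactly
the operations those networks need: broadcast arithmetic, batched matmul,
same-padded strided 2-D convolution via an im2col/col2im pair, leaky ReLU,
sigmoid, log, absolute value, reductions, channel concatenation, horizontal
flip and nearest-neighbour 2x upsampling.

All arrays are ``float32`` unless the caller says otherwise.  Gradients are
accumulated in ``Tensor.grad`` by :meth:`Tensor.backward`, which walks a
topological order of the recorded graph.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "conv2d", "concat"]


def _as_array(x, dtype=np.float32):
    if isinstance(x, Tensor):
        raise TypeError("expected a raw array, got a Tensor")
    return np.asarray(x, dtype=dtype)


class Tensor:
    """A numpy array plus the closure that backpropagates into its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = data if isinstance(data, np.ndarray) else _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self):
        return Tensor(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _unbroadcast(grad, shape):
        """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
        while grad.ndim > len(shape):
            grad = grad.sum(axis=0)
        for ax, n in enumerate(shape):
            if n == 1 and grad.shape[ax] != 1:
                grad = grad.sum(axis=ax, keepdims=True)
        return grad

    def _coerce(self, other):
        return other if isinstance(other, Tensor) else Tensor(_as_array(other))

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self.grad += self._unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += self._unbroadcast(g, other.data.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += -g

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            if self.requires_grad:
                self.grad += self._unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += self._unbroadcast(g * self.data, other.data.shape)

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def matmul(self, other):
        other = self._coerce(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self.grad += self._unbroadcast(ga, self.data.shape)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other.grad += self._unbroadcast(gb, other.data.shape)

        out._backward = backward
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def leaky_relu(self, slope=0.2):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += np.where(mask, g, np.float32(slope) * g)

        out._backward = backward
        return out

    def sigmoid(self):
        y = (1.0 / (1.0 + np.exp(-self.data))).astype(self.data.dtype)
        out = Tensor(y, parents=(self,))

        def backward(g):
            # captures the value array, not the output Tensor: keeping the
            # graph acyclic lets refcounting free whole graphs promptly
            if self.requires_grad:
                self.grad += g * y * (1.0 - y)

        out._backward = backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += g / self.data

        out._backward = backward
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += g * sign

        out._backward = backward
        return out

    def clip(self, lo, hi):
        """Clamp values; gradient passes through only inside [lo, hi]."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += g * inside

        out._backward = backward
        return out

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(
            np.asarray(self.data.sum(axis=axis, keepdims=keepdims)),
            parents=(self,),
        )

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        out._backward = backward
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += np.swapaxes(g, a, b)

        out._backward = backward
        return out

    def flip_lr(self):
        """Reverse the last (width) axis — the left-right mirror."""
        out = Tensor(self.data[..., ::-1].copy(), parents=(self,))

        def backward(g):
            if self.requires_grad:
                self.grad += g[..., ::-1]

        out._backward = backward
        return out

    def upsample2(self):
        """Nearest-neighbour 2x upsampling of an (N, C, H, W) tensor."""
        out = Tensor(
            self.data.repeat(2, axis=2).repeat(2, axis=3), parents=(self,)
        )

        def backward(g):
            if self.requires_grad:
                n, c, h, w = self.data.shape
                self.grad += g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))

        out._backward = backward
        return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(_as_array(data), requires_grad=True)


# -- convolution -----------------------------------------------------------

def _im2col(x, k, stride):
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) with same-style padding k//2."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    ho = (h + 2 * p - k) // stride + 1
    wo = (w + 2 * p - k) // stride + 1
    cols = np.empty((n, c, k, k, ho, wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[
                :, :, i : i + ho * stride : stride, j : j + wo * stride : stride
            ]
    return cols.reshape(n, c * k * k, ho * wo), (ho, wo)


def _col2im(cols, x_shape, k, stride):
    n, c, h, w = x_shape
    p = k // 2
    ho = (h + 2 * p - k) // stride + 1
    wo = (w + 2 * p - k) // stride + 1
    cols = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[
                :, :, i : i + ho * stride : stride, j : j + wo * stride : stride
            ] += cols[:, :, i, j]
    return xp[:, :, p : p + h, p : p + w]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride=1):
    """Same-padded 2-D convolution (cross-correlation) on (N, C, H, W).

    The im2col buffer is rebuilt during backward rather than kept alive,
    so peak memory stays proportional to the activations."""
    cout, cin, k, _ = weight.data.shape
    cols, (ho, wo) = _im2col(x.data, k, stride)
    wmat = weight.data.reshape(cout, -1)
    y = np.matmul(wmat, cols).reshape(x.data.shape[0], cout, ho, wo)
    del cols
    if bias is not None:
        y = y + bias.data.reshape(1, -1, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(y, parents=parents)

    def backward(g):
        gflat = g.reshape(g.shape[0], cout, -1)
        if weight.requires_grad:
            cols_b, _ = _im2col(x.data, k, stride)
            weight.grad += np.einsum(
                "ncl,nkl->ck", gflat, cols_b, optimize=True
            ).reshape(weight.data.shape)
            del cols_b
        if bias is not None and bias.requires_grad:
            bias.grad += g.sum(axis=(0, 2, 3))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gflat)
            x.grad += _col2im(gcols, x.data.shape, k, stride)

    out._backward = backward
    return out


def concat(tensors, axis=1):
    splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
    )

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t.grad += piece

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a list of Parameters."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
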