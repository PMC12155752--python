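"""Tensor with reverse-mode autodiff and the ops needed by the models.

Arrays are float32 throughout (training at this scale is memory-bandwidth
bound and does not need double precision); shapes follow the channel-first convention
(N, C, X, Y, Z) for volumetric data and (N, F) for dense heads.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Tensor:
    """An ndarray plus gradient and backward tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        # break the closure<->tensor reference cycles immediately so the
        # large im2col buffers captured by the tape are freed by refcount,
        # not by an eventual gen-2 garbage collection
        for t in topo:
            t._backward = None
            t._prev = ()

    # ---- basic arithmetic (scalar/broadcast-free paths only where needed) ----

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd():
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd():
            if self.requires_grad or self._prev:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def item(self) -> float:
        return float(self.data)


def release_graph(t: "Tensor") -> None:
    """Drop the backward tape below ``t`` (for forward-only passes).

    Breaks the closure reference cycles so large conv buffers are freed by
    reference counting instead of waiting for the cyclic collector.
    """
    stack, seen = [t], set()
    while stack:
        node = stack.pop()
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.extend(node._prev)
        node._backward = None
        node._prev = ()


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _prev=(x,))

    def bwd():
        x._accum(out.grad * (x.data > 0))

    out._backward = bwd
    return out


def sigmoid(x: Tensor) -> Tensor:
    from scipy.special import expit

    s = expit(x.data)
    out = Tensor(s, _prev=(x,))

    def bwd():
        x._accum(out.grad * s * (1.0 - s))

    out._backward = bwd
    return out


def l1_loss(a: Tensor, b: Tensor) -> Tensor:
    """Mean absolute difference over all elements (scalar output)."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    diff = a.data - b.data
    out = Tensor(np.abs(diff).mean(), _prev=(a, b))
    n = diff.size

    def bwd():
        g = out.grad * np.sign(diff) / n
        if a.requires_grad or a._prev:
            a._accum(g)
        if b.requires_grad or b._prev:
            b._accum(-g)

    out._backward = bwd
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 1) -> Tensor:
    """3D convolution, kernel (Cout, Cin, k, k, k), symmetric zero padding.

    Lowered to a single GEMM via im2col; the backward pass reuses the
    materialised column matrix for the weight gradient and scatters the
    column gradient back with a k^3 shifted-slice loop.
    """
    N, Cin, X, Y, Z = x.data.shape
    Cout, Cin2, k, _, _ = w.data.shape
    assert Cin == Cin2, (Cin, Cin2)
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    Xo = (X + 2 * p - k) // s + 1
    Yo = (Y + 2 * p - k) // s + 1
    Zo = (Z + 2 * p - k) // s + 1
    M = N * Xo * Yo * Zo
    cols = np.empty((Cin, k, k, k, N, Xo, Yo, Zo), dtype=DTYPE)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                cols[:, i, j, l] = xp[
                    :, :, i:i + s * Xo:s, j:j + s * Yo:s, l:l + s * Zo:s
                ].transpose(1, 0, 2, 3, 4)
    colmat = cols.reshape(Cin * k ** 3, M)
    wmat = w.data.reshape(Cout, -1)
    out_data = (wmat @ colmat).reshape(Cout, N, Xo, Yo, Zo)
    out_data += b.data[:, None, None, None, None]
    out = Tensor(np.ascontiguousarray(out_data.transpose(1, 0, 2, 3, 4)),
                 _prev=(x, w, b))

    def bwd():
        gmat = np.ascontiguousarray(
            out.grad.transpose(1, 0, 2, 3, 4)).reshape(Cout, M)
        if w.requires_grad:
            w._accum((gmat @ colmat.T).reshape(w.data.shape))
        if b.requires_grad:
            b._accum(gmat.sum(axis=1))
        if x.requires_grad or x._prev:
            dcols = (wmat.T @ gmat).reshape(Cin, k, k, k, N, Xo, Yo, Zo)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        dxp[:, :, i:i + s * Xo:s, j:j + s * Yo:s, l:l + s * Zo:s] += \
                            dcols[:, i, j, l].transpose(1, 0, 2, 3, 4)
            x._accum(dxp[:, :, p:p + X, p:p + Y, p:p + Z] if p else dxp)

    out._backward = bwd
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling of the three spatial axes."""
    d = np.repeat(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), 2, axis=4)
    out = Tensor(d, _prev=(x,))
    N, C, X, Y, Z = x.data.shape

    def bwd():
        g = out.grad.reshape(N, C, X, 2, Y, 2, Z, 2).sum(axis=(3, 5, 7))
        x._accum(g)

    out._backward = bwd
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(np.concatenate([a.data, b.data], axis=1), _prev=(a, b))
    ca = a.data.shape[1]

    def bwd():
        if a.requires_grad or a._prev:
            a._accum(out.grad[:, :ca])
        if b.requires_grad or b._prev:
            b._accum(out.grad[:, ca:])

    out._backward = bwd
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, X, Y, Z) -> (N, C) spatial mean."""
    out = Tensor(x.data.mean(axis=(2, 3, 4)), _prev=(x,))
    nvox = int(np.prod(x.data.shape[2:]))

    def bwd():
        g = (out.grad / nvox)[:, :, None, None, None]
        x._accum(np.broadcast_to(g, x.data.shape).copy())

    out._backward = bwd
    return out


def layer_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Parameter-free normalisation over the channel/feature axis (axis 1).

    For (N, F) inputs this is classic layer normalisation of the feature
    vector; for (N, C, X, Y, Z) feature maps it normalises each voxel's
    channel vector, keeping activation scales bounded through the encoder
    regardless of what pretraining does to the weights.
    """
    mu = x.data.mean(axis=1, keepdims=True)
    var = x.data.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv
    out = Tensor(y, _prev=(x,))

    def bwd():
        g = out.grad
        gm = g.mean(axis=1, keepdims=True)
        gym = (g * y).mean(axis=1, keepdims=True)
        x._accum((g - gm - y * gym) * inv)

    out._backward = bwd
    return out


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """(N, Fin) @ (Fin, Fout) + (Fout,)."""
    out = Tensor(x.data @ w.data + b.data, _prev=(x, w, b))

    def bwd():
        g = out.grad
        if x.requires_grad or x._prev:
            x._accum(g @ w.data.T)
        if w.requires_grad:
            w._accum(x.data.T @ g)
        if b.requires_grad:
            b._accum(g.sum(axis=0))

    out._backward = bwd
    return out


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer targets against raw logits (N, K)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = len(targets)
    nll = -np.log(np.clip(probs[np.arange(n), targets], 1e-300, None)).mean()
    out = Tensor(nll, _prev=(logits,))

    def bwd():
        g = probs.copy()
        g[np.arange(n), targets] -= 1.0
        logits._accum(out.grad * g / n)

    out._backward = bwd
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)
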