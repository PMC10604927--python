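"""A compact reverse-mode autodiff engine on numpy arrays.

Just enough machinery for small encoder–decoder segmentation networks on
one CPU: NCHW tensors, stride-1 2-D convolution, 2x2 max pooling,
nearest-neighbor upsampling, channel concatenation, global max pooling,
broadcast-aware elementwise arithmetic, ReLU/sigmoid, and an Adam
optimizer.  Gradients flow through a recorded tape (topological sort of
the computation graph).  Everything is float32 (the precision
budget of these small nets) and single-threaded deterministic.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "Module", "Conv2d", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum-reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # ---- elementwise arithmetic (broadcast-aware) ----
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    # ---- reductions / activations ----
    def sum(self):
        def bw(g):
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(self.data.sum(), (self,), bw)

    def mean(self):
        n = self.data.size

        def bw(g):
            self._accum(np.broadcast_to(g / n, self.shape).copy())

        return Tensor._make(self.data.mean(), (self,), bw)

    def relu(self):
        pos = self.data > 0

        def bw(g):
            self._accum(g * pos)

        return Tensor._make(self.data * pos, (self,), bw)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), bw)

    # ---- backprop driver ----
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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


# ---- spatial ops (NCHW) ----

def conv2d(x: Tensor, weight: Tensor, bias: Tensor, pad: int) -> Tensor:
    """Stride-1 2-D convolution; weight (F, C, kh, kw), bias (F,).

    Computed as a sum of per-offset einsum contractions over shifted views
    of the padded input — faster than an im2col copy at these channel
    counts — with a backward pass that mirrors the offsets exactly.
    """
    n, c, h, w = x.shape
    f, _, kh, kw = weight.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    ho, wo = h + 2 * pad - kh + 1, w + 2 * pad - kw + 1
    out = np.empty((n, f, ho, wo), dtype=np.float32)
    out[:] = bias.data[None, :, None, None]
    for i in range(kh):
        for j in range(kw):
            out += np.einsum(
                "nchw,fc->nfhw", xp[:, :, i : i + ho, j : j + wo],
                weight.data[:, :, i, j], optimize=True,
            )

    def bw(g):
        if bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        dxp = np.zeros_like(xp) if x.requires_grad else None
        dW = np.empty_like(weight.data) if weight.requires_grad else None
        for i in range(kh):
            for j in range(kw):
                view = xp[:, :, i : i + ho, j : j + wo]
                if dW is not None:
                    dW[:, :, i, j] = np.einsum("nfhw,nchw->fc", g, view, optimize=True)
                if dxp is not None:
                    dxp[:, :, i : i + ho, j : j + wo] += np.einsum(
                        "nfhw,fc->nchw", g, weight.data[:, :, i, j], optimize=True
                    )
        if dW is not None:
            weight._accum(dW)
        if dxp is not None:
            x._accum(dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp)

    return Tensor._make(out, (x, weight, bias), bw)


def maxpool2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    ho, wo = h // 2, w // 2
    xr = x.data[:, :, : ho * 2, : wo * 2].reshape(n, c, ho, 2, wo, 2)
    xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dxr = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dx = dxr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(dx.reshape(n, c, ho * 2, wo * 2))

    return Tensor._make(out, (x,), bw)


def upsample2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        n, c, h2, w2 = g.shape
        x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bw)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.shape[1]

    def bw(g):
        if a.requires_grad:
            a._accum(g[:, :ca])
        if b.requires_grad:
            b._accum(g[:, ca:])

    return Tensor._make(np.concatenate([a.data, b.data], axis=1), (a, b), bw)


def global_maxpool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C, 1, 1) channel-wise spatial maximum."""
    n, c, h, w = x.shape
    flat = x.data.reshape(n, c, -1)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1).reshape(n, c, 1, 1)

    def bw(g):
        dflat = np.zeros((n, c, h * w))
        np.put_along_axis(dflat, idx[..., None], g.reshape(n, c, 1), axis=-1)
        x._accum(dflat.reshape(n, c, h, w))

    return Tensor._make(out, (x,), bw)


# ---- modules ----

class Module:
    """Minimal parameter container with recursive discovery."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays, strict=True):
            p.data = a.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    """Conv layer with Kaiming-style fan-in init; pad keeps size for odd k."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        fan_in = in_ch * k * k
        self.weight = Tensor(
            rng.standard_normal((out_ch, in_ch, k, k)) * np.sqrt(2.0 / fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
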