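"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the worsening classifier needs: broadcasted
arithmetic, matmul, same-padding 2-D convolution, sigmoid/tanh/exp/log,
reductions, reshape, channel slicing and concatenation.  Gradients are
accumulated by topological-order backward passes; correctness is pinned by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum grad over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph mechanics ----------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()
        stack: list[tuple["Tensor", bool]] = [(self, False)]
        while stack:  # iterative DFS; BPTT graphs outgrow the recursion limit
            t, done = stack.pop()
            if not t.requires_grad:
                continue
            if done:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                stack.append((p, False))
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.requires_grad:
            if self.grad is None:
                self.grad = np.zeros_like(self.data)
            self.grad += grad

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))
        return Tensor(self.data + other.data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))
        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __matmul__(self, other):
        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    def pow_const(self, e: float):
        def bw(g):
            self._accum(g * e * self.data ** (e - 1))
        return Tensor(self.data ** e, parents=(self,), backward=bw)

    def sqrt(self):
        return self.pow_const(0.5)

    # -- nonlinearities -----------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            self._accum(g * s * (1 - s))
        return Tensor(s, parents=(self,), backward=bw)

    def tanh(self):
        v = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1 - v ** 2))
        return Tensor(v, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)
        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    # -- shape / reduction --------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            self._accum(g.reshape(old))
        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())
        return Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                      parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def slice_channels(self, start: int, stop: int):
        """Slice axis 1 (channels) of an (N, C, ...) tensor."""
        def bw(g):
            full = np.zeros_like(self.data)
            full[:, start:stop] = g
            self._accum(full)
        return Tensor(self.data[:, start:stop], parents=(self,), backward=bw)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    """Concatenate along axis 1."""
    sizes = [t.shape[1] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            t._accum(g[:, a:b])
    return Tensor(np.concatenate([t.data for t in tensors], axis=1),
                  parents=tuple(tensors), backward=bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor, padding: int = 1) -> Tensor:
    """Stride-1 2-D convolution: x (N,C,H,W), w (O,C,kh,kw), b (O,)."""
    N, C, H, W = x.shape
    O, _, kh, kw = w.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,Ho,Wo,kh,kw
    y = np.einsum("nchwab,ocab->nohw", win, w.data, optimize=True)
    y += b.data[None, :, None, None]

    def bw(g):
        w._accum(np.einsum("nchwab,nohw->ocab", win, g, optimize=True))
        b._accum(g.sum(axis=(0, 2, 3)))
        gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
        wf = w.data[:, :, ::-1, ::-1]
        dxp = np.einsum("nohwab,ocab->nchw", gwin, wf, optimize=True)
        x._accum(dxp[:, :, padding:padding + H, padding:padding + W])
    return Tensor(y, parents=(x, w, b), backward=bw)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-2,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g ** 2
            mh = m / (1 - self.b1 ** self.t)
            vh = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
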