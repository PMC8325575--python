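"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the reconstruction network: tensors carrying a
backward closure, the handful of dense ops the architecture uses (stride-1
convolutions, leaky-ReLU/ReLU/sigmoid, channel concatenation, global
average pooling, fully connected layers, broadcast multiply/add) and an
Adam optimizer.  Tomographic layers (forward projection, FBP, sinogram
fusion) plug in through :func:`custom_op`, which lets them declare the
surrogate derivatives the unrolled method prescribes instead of the true
adjoints.

All data is float64.  Feature maps are ``(N, C, H, W)``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


class Tensor:
    """Array node in the backward graph."""

    __slots__ = ("data", "grad", "parents", "bw", "requires_grad")

    def __init__(
        self,
        data,
        parents: Sequence["Tensor"] = (),
        bw: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.parents = tuple(parents)
        self.bw = bw
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in self.parents
        )

    @property
    def shape(self):
        return self.data.shape

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable tensor's ``.grad``."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))

        self.grad = (
            np.ones_like(self.data) if seed is None else np.asarray(seed, float)
        )
        for node in reversed(topo):
            if node.bw is None or node.grad is None:
                continue
            for parent, g in zip(node.parents, node.bw(node.grad)):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    # copy: backward closures may hand the same array to
                    # several parents (e.g. add), and we accumulate in place
                    parent.grad = np.array(g, dtype=float)
                else:
                    parent.grad += g


class Parameter(Tensor):
    """Learnable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def custom_op(
    data: np.ndarray,
    parents: Sequence[Tensor],
    bw: Callable[[np.ndarray], Sequence[np.ndarray | None]],
) -> Tensor:
    """Wrap an externally computed forward value with a declared backward."""
    return Tensor(data, parents, bw)


# ---------------------------------------------------------------------------
# elementwise and shape ops

def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data + b.data, (a, b), lambda g: (g, g))


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data - b.data, (a, b), lambda g: (g, -g))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Broadcasting elementwise product (used for attention calibration)."""

    def bw(g):
        return (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape))

    return Tensor(a.data * b.data, (a, b), bw)


def scale(a: Tensor, c: float) -> Tensor:
    return Tensor(a.data * c, (a,), lambda g: (g * c,))


def shift(a: Tensor, c: float) -> Tensor:
    return Tensor(a.data + c, (a,), lambda g: (g,))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def reshape(a: Tensor, shape: tuple) -> Tensor:
    old = a.data.shape
    return Tensor(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))


# ---------------------------------------------------------------------------
# activations

def leaky_relu(a: Tensor, slope: float = 0.01) -> Tensor:
    mask = a.data > 0
    factor = np.where(mask, 1.0, slope)
    return Tensor(a.data * factor, (a,), lambda g: (g * factor,))


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return Tensor(a.data * mask, (a,), lambda g: (g * mask,))


def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-a.data))
    return Tensor(y, (a,), lambda g: (g * y * (1.0 - y),))


# ---------------------------------------------------------------------------
# dense layers

def conv2d(x: Tensor, w: Tensor, b: Tensor | None, pad: int) -> Tensor:
    """Stride-1 2D correlation, NCHW x (Cout, Cin, kh, kw); im2col + GEMM."""
    n, cin, h, wd = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    assert cin == cin2, "channel mismatch"
    ho, wo = h + 2 * pad - kh + 1, wd + 2 * pad - kw + 1

    if kh == kw == 1 and pad == 0:
        # 1x1 convolution: a plain channel mixing GEMM
        xf = x.data.transpose(0, 2, 3, 1).reshape(-1, cin)
        wf = w.data.reshape(cout, cin)
        out = (xf @ wf.T).reshape(n, h, wd, cout).transpose(0, 3, 1, 2)
        if b is not None:
            out += b.data[None, :, None, None]

        def bw1(g):
            gf = g.transpose(0, 2, 3, 1).reshape(-1, cout)
            gx = (gf @ wf).reshape(n, h, wd, cin).transpose(0, 3, 1, 2)
            gw = (gf.T @ xf).reshape(w.data.shape)
            if b is not None:
                return gx, gw, g.sum(axis=(0, 2, 3))
            return gx, gw

        parents = (x, w, b) if b is not None else (x, w)
        return Tensor(out, parents, bw1)

    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, ho, wo, cin, kh, kw))
    for i in range(kh):
        for j in range(kw):
            cols[..., i, j] = xp[:, :, i : i + ho, j : j + wo].transpose(0, 2, 3, 1)
    cols2 = cols.reshape(n * ho * wo, cin * kh * kw)
    wf = w.data.reshape(cout, -1)
    out = (cols2 @ wf.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out += b.data[None, :, None, None]

    def bw(g):
        gf = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        gw = (gf.T @ cols2).reshape(w.data.shape)
        gcols = (gf @ wf).reshape(n, ho, wo, cin, kh, kw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + ho, j : j + wo] += gcols[..., i, j].transpose(
                    0, 3, 1, 2
                )
        gx = gxp[:, :, pad : pad + h, pad : pad + wd] if pad else gxp
        if b is not None:
            return gx, gw, g.sum(axis=(0, 2, 3))
        return gx, gw

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(out, parents, bw)


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Fully connected layer: (N, Cin) x (Cout, Cin) -> (N, Cout)."""
    out = x.data @ w.data.T
    if b is not None:
        out = out + b.data

    def bw(g):
        gx = g @ w.data
        gw = g.T @ x.data
        if b is not None:
            return gx, gw, g.sum(axis=0)
        return gx, gw

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor(out, parents, bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = x.data.shape
    area = h * w

    def bw(g):
        return (np.broadcast_to(g[:, :, None, None] / area, x.data.shape),)

    return Tensor(x.data.mean(axis=(2, 3)), (x,), bw)


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - np.asarray(target, float)
    n = diff.size

    def bw(g):
        return (g * 2.0 * diff / n,)

    return Tensor(np.mean(diff**2), (pred,), bw)


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    """Adam with configurable first-moment decay (``beta1``)."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 5e-4,
        beta1: float = 0.99,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
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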