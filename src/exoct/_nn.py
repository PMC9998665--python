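"""Minimal reverse-mode autodiff over numpy for small convolutional nets.

Only the operations the nested-skip segmenter needs are provided: 3x3
same-padding convolution (im2col), 1x1 convolution, ReLU, 2x2 max pooling,
2x nearest-neighbour upsampling, channel concatenation and sigmoid. Tensors
form a tape; ``backward`` walks it in reverse topological order. Everything
is float32 and fully deterministic given a seeded ``numpy`` generator.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    """A node in the computation tape: value, gradient, and parents."""

    __slots__ = ("data", "grad", "parents", "_backward", "is_param")

    def __init__(
        self,
        data: np.ndarray,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
        is_param: bool = False,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.parents = tuple(parents)
        self._backward = backward
        self.is_param = is_param

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g


def backward(root: Tensor, grad: np.ndarray) -> None:
    """Backpropagate ``grad`` (dL/droot) through the tape below ``root``."""
    topo: List[Tensor] = []
    seen = set()
    stack: List[Tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            stack.append((p, False))
    root.accumulate(np.asarray(grad, dtype=np.float32))
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def zero_grads(params: Sequence[Tensor]) -> None:
    for p in params:
        p.grad = None


# ---------------------------------------------------------------------------
# operations; activations are (N, C, H, W)

def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, H, W, C*9) patches with zero same-padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    v = sliding_window_view(xp, (3, 3), axis=(2, 3))  # N,C,H,W,3,3
    return np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h, w, c * 9)


def _conv3_raw(x: np.ndarray, w: np.ndarray, b: Optional[np.ndarray]) -> np.ndarray:
    """Forward 3x3 convolution. ``w`` is (K, C, 3, 3)."""
    n, c, h, wid = x.shape
    k = w.shape[0]
    cols = _im2col3(x)
    wmat = w.transpose(1, 2, 3, 0).reshape(c * 9, k)
    y = cols.reshape(-1, c * 9) @ wmat
    y = y.reshape(n, h, wid, k).transpose(0, 3, 1, 2)
    if b is not None:
        y += b[None, :, None, None]
    return np.ascontiguousarray(y)


def conv3(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    y = _conv3_raw(x.data, w.data, b.data)
    n, c, h, wid = x.data.shape
    k = w.data.shape[0]

    def bwd(gy: np.ndarray):
        b.accumulate(gy.sum(axis=(0, 2, 3)))
        cols = _im2col3(x.data).reshape(-1, c * 9)
        gflat = gy.transpose(0, 2, 3, 1).reshape(-1, k)
        gw = (cols.T @ gflat).reshape(c, 3, 3, k).transpose(3, 0, 1, 2)
        w.accumulate(gw)
        # dL/dx = conv(gy, rot180(w) with channels swapped)
        w_rot = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        x.accumulate(_conv3_raw(gy, w_rot, None))

    return Tensor(y, parents=(x, w, b), backward=bwd)


def conv1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1x1 convolution; ``w`` is (K, C)."""
    y = np.einsum("nchw,kc->nkhw", x.data, w.data) + b.data[None, :, None, None]

    def bwd(gy: np.ndarray):
        b.accumulate(gy.sum(axis=(0, 2, 3)))
        w.accumulate(np.einsum("nkhw,nchw->kc", gy, x.data))
        x.accumulate(np.einsum("nkhw,kc->nchw", gy, w.data))

    return Tensor(y, parents=(x, w, b), backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    y = x.data * mask

    def bwd(gy: np.ndarray):
        x.accumulate(gy * mask)

    return Tensor(y, parents=(x,), backward=bwd)


def maxpool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(gy: np.ndarray):
        g4 = np.zeros_like(xr)
        np.put_along_axis(g4, idx[..., None], gy[..., None], axis=-1)
        g = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x.accumulate(g.reshape(n, c, h, w))

    return Tensor(y, parents=(x,), backward=bwd)


def upsample2(x: Tensor) -> Tensor:
    y = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bwd(gy: np.ndarray):
        n, c, h2, w2 = gy.shape
        x.accumulate(gy.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor(y, parents=(x,), backward=bwd)


def concat(xs: Sequence[Tensor]) -> Tensor:
    y = np.concatenate([t.data for t in xs], axis=1)
    splits = np.cumsum([t.data.shape[1] for t in xs])[:-1]

    def bwd(gy: np.ndarray):
        for t, g in zip(xs, np.split(gy, splits, axis=1)):
            t.accumulate(g)

    return Tensor(y, parents=tuple(xs), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))

    def bwd(gy: np.ndarray):
        x.accumulate(gy * y * (1.0 - y))

    return Tensor(y, parents=(x,), backward=bwd)


# ---------------------------------------------------------------------------

def kaiming_conv(rng: np.random.Generator, k: int, c: int, ksize: int) -> np.ndarray:
    """He-normal weights for a conv layer with ``c * ksize**2`` fan-in."""
    fan_in = c * ksize * ksize
    w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, c, ksize, ksize))
    if ksize == 1:
        w = w[:, :, 0, 0]
    return w.astype(np.float32)


class Adam:
    """Standard Adam with bias correction; ``lr`` may be changed between steps."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
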