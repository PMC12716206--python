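"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the primitives the inpainting encoder–decoders need:
broadcast arithmetic, ReLU/sigmoid, same-padded 2D convolution (via
im2col and matmul), 2x2 max-pooling, nearest-neighbour 2x upsampling,
channel concatenation, global mean, and a valid-mode box-mean filter
(integral-image based) used by the differentiable structural-similarity
loss.  Tensors preserve the float dtype of their payload (float32 for
training throughput, float64 for gradient checking); gradients are
accumulated into ``.grad`` by :meth:`Tensor.backward` over a
topologically sorted graph.

The engine is intentionally small rather than general: stride is fixed
at 1, pooling at 2, kernels are odd-sized, and only the ops used by the
models carry backward rules.  Each op's gradient is verified against
central differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "maxpool2", "upsample2", "concat", "relu",
           "sigmoid", "mean_all", "box_mean_valid", "as_tensor", "Adam"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _bw=None):
        d = np.asarray(data)
        if d.dtype not in (np.float32, np.float64):
            d = d.astype(np.float64)
        self.data = d
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._bw = _bw

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            if node.requires_grad or node._parents:
                node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    # ---- arithmetic -------------------------------------------------
    def __add__(self, other):
        return _binop(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binop(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binop(self, other, np.multiply,
                      lambda g, a, b: (g * b.data, g * a.data))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binop(self, other, np.divide,
                      lambda g, a, b: (g / b.data, -g * a.data / b.data**2))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, k: float):
        out = Tensor(self.data**k, _parents=(self,))

        def bw(g):
            _accum(self, g * k * self.data ** (k - 1))

        out._bw = bw
        return out

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bw(g):
            _accum(self, g.reshape(orig))

        out._bw = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _accum(node: Tensor, g: np.ndarray) -> None:
    if node.grad is None:
        node.grad = np.zeros_like(node.data)
    node.grad += _unbroadcast(g, node.data.shape)


def _binop(a, b, fwd, grads) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(fwd(a.data, b.data), _parents=(a, b))

    def bw(g):
        ga, gb = grads(g, a, b)
        _accum(a, ga)
        _accum(b, gb)

    out._bw = bw
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _parents=(x,))

    def bw(g):
        _accum(x, g * (x.data > 0))

    out._bw = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, _parents=(x,))

    def bw(g):
        _accum(x, g * s * (1.0 - s))

    out._bw = bw
    return out


def mean_all(x: Tensor) -> Tensor:
    out = Tensor(x.data.mean(), _parents=(x,))

    def bw(g):
        _accum(x, np.full_like(x.data, float(g) / x.data.size))

    out._bw = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 convolution (cross-correlation), odd kernels.

    x: (N, C, H, W); w: (F, C, kh, kw); b: (F,) or None -> (N, F, H, W).
    """
    N, C, H, W = x.data.shape
    F, C2, kh, kw = w.data.shape
    if C2 != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {C2}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * kh * kw)
    out_d = cols @ w.data.reshape(F, -1).T
    if b is not None:
        out_d = out_d + b.data
    out_d = out_d.reshape(N, H, W, F).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_d, _parents=parents)

    def bw(g):
        gcols = g.transpose(0, 2, 3, 1).reshape(N * H * W, F)
        _accum(w, (gcols.T @ cols).reshape(F, C, kh, kw))
        if b is not None:
            _accum(b, gcols.sum(axis=0))
        # grad wrt input = same-padded correlation with spatially flipped,
        # channel-transposed kernel (valid for odd kernels, stride 1)
        gp = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
        gcols2 = gwin.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, F * kh * kw)
        wf = np.flip(w.data, axis=(2, 3)).transpose(1, 0, 2, 3).reshape(C, F * kh * kw)
        _accum(x, (gcols2 @ wf.T).reshape(N, H, W, C).transpose(0, 3, 1, 2))

    out._bw = bw
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; ties resolve to the first element."""
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    x6 = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    flat = x6.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0],
                 _parents=(x,))

    def bw(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        _accum(x, gf.reshape(N, C, H // 2, W // 2, 2, 2)
               .transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H, W))

    out._bw = bw
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    N, C, H, W = x.data.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), _parents=(x,))

    def bw(g):
        _accum(x, g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    out._bw = bw
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis (axis 1)."""
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), _parents=(a, b))

    def bw(g):
        _accum(a, g[:, :ca])
        _accum(b, g[:, ca:])

    out._bw = bw
    return out


def _boxsum_valid(a: np.ndarray, win: int) -> np.ndarray:
    """Valid-mode sliding window sum over the last two axes via integral image."""
    c = a.cumsum(axis=-2).cumsum(axis=-1)
    pad = [(0, 0)] * (a.ndim - 2) + [(1, 0), (1, 0)]
    c = np.pad(c, pad)
    return (c[..., win:, win:] - c[..., :-win, win:]
            - c[..., win:, :-win] + c[..., :-win, :-win])


def box_mean_valid(x: Tensor, win: int) -> Tensor:
    """Valid-mode box-mean filter over the last two axes (window ``win``)."""
    H, W = x.data.shape[-2:]
    if win > H or win > W:
        raise ValueError(f"window {win} larger than image {H}x{W}")
    out = Tensor(_boxsum_valid(x.data, win) / win**2, _parents=(x,))

    def bw(g):
        pad = [(0, 0)] * (g.ndim - 2) + [(win - 1, win - 1), (win - 1, win - 1)]
        _accum(x, _boxsum_valid(np.pad(g, pad), win) / win**2)

    out._bw = bw
    return out


class Adam:
    """Adaptive-moment optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
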