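"""Minimal NumPy neural-network layers with explicit backward passes.

Channels-last layout throughout: dense inputs are ``(rows, features)``,
image inputs are ``(B, H, W, C)``.  Layers cache whatever their backward
pass needs; gradients accumulate into ``Param.grad`` until the optimizer's
``zero_grad``.  Everything is float32 and deterministic given the RNG used
at construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Module", "Dense", "ReLU", "Sequential", "Conv2d",
    "MaxPool2", "UpsampleNearest2", "resize_matrix", "BilinearResize", "Adam",
]

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    """Base: recursively collects Params from attributes and sub-modules."""

    def params(self) -> list[Param]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
                    elif isinstance(item, Param):
                        out.append(item)
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]

    def load_state_arrays(self, arrays) -> None:
        own = self.params()
        if len(arrays) != len(own):
            raise ValueError(f"expected {len(own)} arrays, got {len(arrays)}")
        for p, a in zip(own, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value = np.asarray(a, dtype=DTYPE).copy()


class Dense(Module):
    """Affine layer ``y = x W + b`` with He-style init (or zero init)."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.W = Param(w)
        self.b = Param(np.zeros(n_out))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return np.where(self._mask, g, 0.0)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class Conv2d(Module):
    """2D convolution, stride 1, zero 'same' padding, square kernel.

    Implemented as im2col + matmul; the backward pass folds the column
    gradient back by accumulating the k*k shifted views.
    """

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, k: int = 3):
        fan_in = k * k * c_in
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.W = Param(rng.standard_normal((fan_in, c_out)) * np.sqrt(2.0 / fan_in))
        self.b = Param(np.zeros(c_out))

    def _im2col(self, xp: np.ndarray, h: int, w: int) -> np.ndarray:
        k = self.k
        cols = np.empty((xp.shape[0], h, w, k * k * self.c_in), dtype=DTYPE)
        idx = 0
        for di in range(k):
            for dj in range(k):
                cols[..., idx:idx + self.c_in] = xp[:, di:di + h, dj:dj + w, :]
                idx += self.c_in
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, _ = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = self._im2col(xp, h, w)
        self._cols = cols.reshape(-1, cols.shape[-1])
        self._shape = (b, h, w)
        y = self._cols @ self.W.value + self.b.value
        return y.reshape(b, h, w, self.c_out)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w = self._shape
        gf = g.reshape(-1, self.c_out)
        self.W.grad += self._cols.T @ gf
        self.b.grad += gf.sum(axis=0)
        gcols = (gf @ self.W.value.T).reshape(b, h, w, self.k * self.k * self.c_in)
        p = self.k // 2
        gxp = np.zeros((b, h + 2 * p, w + 2 * p, self.c_in), dtype=DTYPE)
        idx = 0
        for di in range(self.k):
            for dj in range(self.k):
                gxp[:, di:di + h, dj:dj + w, :] += gcols[..., idx:idx + self.c_in]
                idx += self.c_in
        return gxp[:, p:p + h, p:p + w, :] if p else gxp


class MaxPool2(Module):
    """2x2 max pooling; input H and W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(b, h // 2, w // 2, c, 4)
        self._argmax = xr.argmax(axis=-1)
        self._shape = (b, h, w, c)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        gx = np.zeros((b, h // 2, w // 2, c, 4), dtype=DTYPE)
        np.put_along_axis(gx, self._argmax[..., None], g[..., None], axis=-1)
        gx = gx.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return gx.reshape(b, h, w, c)


class UpsampleNearest2(Module):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w, c = g.shape
        return g.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Dense 1D bilinear interpolation matrix (n_out, n_in), half-pixel
    centers, edge-clamped.  ``n_out == n_in`` yields the exact identity, so
    a resize at scale 1.0 is a bit-wise no-op."""
    if n_in == n_out:
        return np.eye(n_in, dtype=DTYPE)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0)
    a = np.zeros((n_out, n_in), dtype=DTYPE)
    rows = np.arange(n_out)
    np.add.at(a, (rows, i0), (1.0 - frac).astype(DTYPE))
    np.add.at(a, (rows, i1), frac.astype(DTYPE))
    return a


class BilinearResize(Module):
    """Separable bilinear resize of (B, H, W, C) images to a target size.

    The target is set per forward call; identity sizes short-circuit so that
    scale-1.0 passes are bit-identical to no resize at all.
    """

    def forward(self, x: np.ndarray, h_out: int, w_out: int) -> np.ndarray:
        b, h, w, c = x.shape
        self._in_shape = (h, w)
        self._identity = (h_out == h and w_out == w)
        if self._identity:
            return x
        self._ah = resize_matrix(h, h_out)
        self._aw = resize_matrix(w, w_out)
        y = np.einsum("oh,bhwc->bowc", self._ah, x, optimize=True)
        return np.einsum("pw,bhwc->bhpc", self._aw, y, optimize=True)

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._identity:
            return g
        gy = np.einsum("pw,bhpc->bhwc", self._aw, g, optimize=True)
        return np.einsum("oh,bowc->bhwc", self._ah, gy, optimize=True)


class Adam:
    """Adam optimizer over a list of Params; lr is mutable for schedules."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
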