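"""Minimal 3D conv-net layers in numpy with explicit backward passes.

Tensors are channel-first: ``(C, X, Y, Z)``.  Each layer caches what its
backward pass needs; ``backward`` consumes the upstream gradient and
accumulates parameter gradients in ``gw``/``gb``.  Convolution is computed
as a sum over kernel offsets of BLAS ``tensordot`` contractions, which
keeps memory at O(volume) instead of the O(volume * kernel) of im2col.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "InstanceNorm3d", "ReLU", "avgpool2", "avgpool2_backward",
           "upsample2", "upsample2_backward"]


class Conv3d:
    """3D convolution, odd kernel, stride 1, 'same' zero padding."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        std = np.sqrt(2.0 / (k ** 3 * cin))
        self.w = rng.normal(0.0, std, size=(k, k, k, cin, cout))
        self.b = np.zeros(cout)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xp = None

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        k, p = self.k, self.k // 2
        C, X, Y, Z = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
        out = np.zeros((self.cout, X, Y, Z))
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, i:i + X, j:j + Y, l:l + Z]
                    out += np.tensordot(self.w[i, j, l], xs, axes=([0], [0]))
        out += self.b[:, None, None, None]
        if cache:
            self._xp = xp
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = self._xp
        X, Y, Z = dout.shape[1:]
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    xs = xp[:, i:i + X, j:j + Y, l:l + Z]
                    self.gw[i, j, l] += np.tensordot(xs, dout, axes=([1, 2, 3], [1, 2, 3]))
                    dxp[:, i:i + X, j:j + Y, l:l + Z] += np.tensordot(
                        self.w[i, j, l], dout, axes=([1], [0])
                    )
        self.gb += dout.sum(axis=(1, 2, 3))
        return dxp[:, p:p + X, p:p + Y, p:p + Z] if p else dxp

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class InstanceNorm3d:
    """Per-channel normalization over the spatial axes with affine scale."""

    eps = 1e-5

    def __init__(self, c: int):
        self.g = np.ones(c)
        self.b = np.zeros(c)
        self.gg = np.zeros_like(self.g)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        mu = x.mean(axis=(1, 2, 3), keepdims=True)
        var = x.var(axis=(1, 2, 3), keepdims=True)
        istd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * istd
        if cache:
            self._cache = (xhat, istd)
        return self.g[:, None, None, None] * xhat + self.b[:, None, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, istd = self._cache
        n = xhat[0].size
        self.gg += (dout * xhat).sum(axis=(1, 2, 3))
        self.gb += dout.sum(axis=(1, 2, 3))
        dxhat = dout * self.g[:, None, None, None]
        # standard normalization backward, fused
        return istd * (
            dxhat
            - dxhat.mean(axis=(1, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
        ) if n > 1 else np.zeros_like(dout)

    def params(self):
        return [(self.g, self.gg), (self.b, self.gb)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        if cache:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


def avgpool2(x: np.ndarray) -> np.ndarray:
    C, X, Y, Z = x.shape
    return x.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2).mean(axis=(2, 4, 6))


def avgpool2_backward(dout: np.ndarray, in_shape) -> np.ndarray:
    up = upsample2(dout)
    return up / 8.0


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    C, X, Y, Z = dout.shape
    return dout.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2).sum(axis=(2, 4, 6))
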