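"""1-D convolution, pooling and upsampling layers on (batch, length, channels).

Convolutions are computed as sums of shifted matmuls — one GEMM per kernel
tap — which keeps the arithmetic in BLAS without an im2col copy. All layers
use 'same'-style padding so lengths are predictable: a dilated conv
preserves length, a strided conv maps L -> ceil(L/stride).
"""

from __future__ import annotations

import numpy as np

from ..errors import ShapeError
from .core import Layer, he_init

__all__ = ["DilatedConv1D", "StridedConv1D", "AvgPool1D", "GlobalAvgPool1D", "Upsample1D"]


class DilatedConv1D(Layer):
    """Length-preserving dilated convolution (stride 1, same padding)."""

    def __init__(self, cin: int, cout: int, kernel: int, dilation: int = 1,
                 rng: np.random.Generator = None, dtype=np.float32):
        self.name = f"dilconv_k{kernel}d{dilation}_{cin}x{cout}"
        self.cin, self.cout, self.k, self.d = cin, cout, kernel, dilation
        rng = rng or np.random.default_rng(0)
        self.W = he_init(rng, (kernel, cin, cout), kernel * cin, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        span = (kernel - 1) * dilation
        self.pl = span // 2
        self.pr = span - self.pl

    @property
    def parameters(self):
        return [self.W, self.b]

    @property
    def gradients(self):
        return [self.dW, self.db]

    def forward(self, x, train=False):
        if x.ndim != 3 or x.shape[2] != self.cin:
            raise ShapeError(f"{self.name}: expected (B, L, {self.cin}), got {x.shape}")
        B, L, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pl, self.pr), (0, 0)))
        self._xp, self._L = xp, L
        y = np.empty((B, L, self.cout), dtype=x.dtype)
        np.copyto(y, self.b)
        for j in range(self.k):
            y += xp[:, j * self.d : j * self.d + L, :] @ self.W[j]
        return y

    def backward(self, dy):
        xp, L = self._xp, self._L
        B = dy.shape[0]
        dy2 = dy.reshape(B * L, self.cout)
        self.db[...] = dy2.sum(axis=0)
        dxp = np.zeros_like(xp)
        for j in range(self.k):
            xs = xp[:, j * self.d : j * self.d + L, :].reshape(B * L, self.cin)
            self.dW[j] = xs.T @ dy2
            dxp[:, j * self.d : j * self.d + L, :] += dy @ self.W[j].T
        return dxp[:, self.pl : self.pl + L, :]


class StridedConv1D(Layer):
    """Downsampling convolution: L -> ceil(L/stride), same-style padding."""

    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 2,
                 rng: np.random.Generator = None, dtype=np.float32):
        self.name = f"conv_k{kernel}s{stride}_{cin}x{cout}"
        self.cin, self.cout, self.k, self.s = cin, cout, kernel, stride
        rng = rng or np.random.default_rng(0)
        self.W = he_init(rng, (kernel, cin, cout), kernel * cin, dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def parameters(self):
        return [self.W, self.b]

    @property
    def gradients(self):
        return [self.dW, self.db]

    def out_len(self, L: int) -> int:
        return -(-L // self.s)  # ceil

    def forward(self, x, train=False):
        if x.ndim != 3 or x.shape[2] != self.cin:
            raise ShapeError(f"{self.name}: expected (B, L, {self.cin}), got {x.shape}")
        B, L, _ = x.shape
        Lout = self.out_len(L)
        pad_total = max((Lout - 1) * self.s + self.k - L, 0)
        pl = pad_total // 2
        pr = pad_total - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        self._xp, self._L, self._pl, self._Lout = xp, L, pl, Lout
        y = np.empty((B, Lout, self.cout), dtype=x.dtype)
        np.copyto(y, self.b)
        for j in range(self.k):
            y += xp[:, j : j + self.s * Lout : self.s, :] @ self.W[j]
        return y

    def backward(self, dy):
        xp, L, pl, Lout = self._xp, self._L, self._pl, self._Lout
        B = dy.shape[0]
        dy2 = dy.reshape(B * Lout, self.cout)
        self.db[...] = dy2.sum(axis=0)
        dxp = np.zeros_like(xp)
        for j in range(self.k):
            xs = xp[:, j : j + self.s * Lout : self.s, :].reshape(B * Lout, self.cin)
            self.dW[j] = xs.T @ dy2
            dxp[:, j : j + self.s * Lout : self.s, :] += dy @ self.W[j].T
        return dxp[:, pl : pl + L, :]


class AvgPool1D(Layer):
    """Non-overlapping average pooling; a ragged tail is dropped."""

    def __init__(self, stride: int):
        self.name = f"avgpool_s{stride}"
        self.s = stride

    def out_len(self, L: int) -> int:
        return L // self.s

    def forward(self, x, train=False):
        B, L, C = x.shape
        Lout = self.out_len(L)
        if Lout == 0:
            raise ShapeError(f"{self.name}: length {L} shorter than pool stride {self.s}")
        self._shape = x.shape
        return x[:, : Lout * self.s, :].reshape(B, Lout, self.s, C).mean(axis=2)

    def backward(self, dy):
        B, L, C = self._shape
        Lout = dy.shape[1]
        dx = np.zeros(self._shape, dtype=dy.dtype)
        dx[:, : Lout * self.s, :] = np.repeat(dy / self.s, self.s, axis=1)
        return dx


class GlobalAvgPool1D(Layer):
    """(B, L, C) -> (B, C) mean over the length axis."""

    name = "global_avgpool"

    def forward(self, x, train=False):
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :] / self._L, self._L, axis=1)


class Upsample1D(Layer):
    """Nearest-neighbour upsampling by an integer factor (for the U-Net decoder)."""

    def __init__(self, factor: int):
        self.name = f"upsample_x{factor}"
        self.f = factor

    def forward(self, x, train=False):
        return np.repeat(x, self.f, axis=1)

    def backward(self, dy):
        B, Lf, C = dy.shape
        L = Lf // self.f
        return dy.reshape(B, L, self.f, C).sum(axis=2)
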