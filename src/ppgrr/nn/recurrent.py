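"""Recurrent layers (LSTM family) with full backpropagation through time.

These back the simplified reference baselines; they loop over time in
Python, so they are intended for short sequences (the baselines first
compress the signal, or are exercised on short windows in tests).
"""

from __future__ import annotations

import numpy as np

from ..errors import ShapeError
from .core import Layer

__all__ = ["LSTM", "BiLSTM", "AdditiveAttention"]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Single-direction LSTM; returns the full sequence or the last state."""

    def __init__(self, cin: int, units: int, return_sequences: bool = False,
                 rng: np.random.Generator = None, dtype=np.float32):
        self.name = f"lstm_{units}"
        self.cin, self.units = cin, units
        self.return_sequences = return_sequences
        rng = rng or np.random.default_rng(0)
        scale = 1.0 / np.sqrt(cin + units)
        self.W = (rng.standard_normal((cin, 4 * units)) * scale).astype(dtype)
        self.U = (rng.standard_normal((units, 4 * units)) * scale).astype(dtype)
        self.b = np.zeros(4 * units, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)

    @property
    def parameters(self):
        return [self.W, self.U, self.b]

    @property
    def gradients(self):
        return [self.dW, self.dU, self.db]

    def forward(self, x, train=False):
        if x.ndim != 3 or x.shape[2] != self.cin:
            raise ShapeError(f"{self.name}: expected (B, L, {self.cin}), got {x.shape}")
        B, L, _ = x.shape
        u = self.units
        h = np.zeros((B, u), dtype=x.dtype)
        c = np.zeros((B, u), dtype=x.dtype)
        self._x = x
        self._cache = []
        hs = np.empty((B, L, u), dtype=x.dtype)
        for t in range(L):
            z = x[:, t, :] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t, :] = h
            self._cache.append((i, f, g, o, c_prev, h_prev, tc))
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        B, L, _ = x.shape
        u = self.units
        self.dW[...] = 0
        self.dU[...] = 0
        self.db[...] = 0
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, u), dtype=x.dtype)
        dc_next = np.zeros((B, u), dtype=x.dtype)
        for t in range(L - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = self._cache[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dy[:, t, :]
            elif t == L - 1:
                dh += dy
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            self.dW += x[:, t, :].T @ dz
            self.dU += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return dx


class BiLSTM(Layer):
    """Forward + backward LSTM passes, outputs concatenated on channels."""

    def __init__(self, cin: int, units: int, return_sequences: bool = False,
                 rng: np.random.Generator = None, dtype=np.float32):
        self.name = f"bilstm_{units}"
        rng = rng or np.random.default_rng(0)
        self.fwd = LSTM(cin, units, return_sequences=return_sequences, rng=rng, dtype=dtype)
        self.bwd = LSTM(cin, units, return_sequences=return_sequences, rng=rng, dtype=dtype)
        self.units = units
        self.return_sequences = return_sequences

    @property
    def parameters(self):
        return self.fwd.parameters + self.bwd.parameters

    @property
    def gradients(self):
        return self.fwd.gradients + self.bwd.gradients

    def forward(self, x, train=False):
        yf = self.fwd.forward(x, train=train)
        yb = self.bwd.forward(x[:, ::-1, :], train=train)
        if self.return_sequences:
            yb = yb[:, ::-1, :]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dy):
        u = self.units
        dyf, dyb = dy[..., :u], dy[..., u:]
        if self.return_sequences:
            dyb = dyb[:, ::-1, :]
        dxf = self.fwd.backward(np.ascontiguousarray(dyf))
        dxb = self.bwd.backward(np.ascontiguousarray(dyb))
        return dxf + dxb[:, ::-1, :]


class AdditiveAttention(Layer):
    """Additive (Bahdanau-style) attention pooling: (B, L, C) -> (B, C)."""

    def __init__(self, cin: int, att_dim: int = 32,
                 rng: np.random.Generator = None, dtype=np.float32):
        self.name = f"attention_{att_dim}"
        rng = rng or np.random.default_rng(0)
        scale = 1.0 / np.sqrt(cin)
        self.Wa = (rng.standard_normal((cin, att_dim)) * scale).astype(dtype)
        self.ba = np.zeros(att_dim, dtype=dtype)
        self.v = (rng.standard_normal(att_dim) / np.sqrt(att_dim)).astype(dtype)
        self.dWa = np.zeros_like(self.Wa)
        self.dba = np.zeros_like(self.ba)
        self.dv = np.zeros_like(self.v)
        self.cin = cin

    @property
    def parameters(self):
        return [self.Wa, self.ba, self.v]

    @property
    def gradients(self):
        return [self.dWa, self.dba, self.dv]

    def forward(self, x, train=False):
        if x.ndim != 3 or x.shape[2] != self.cin:
            raise ShapeError(f"{self.name}: expected (B, L, {self.cin}), got {x.shape}")
        s = np.tanh(x @ self.Wa + self.ba)          # (B, L, a)
        e = s @ self.v                              # (B, L)
        e = e - e.max(axis=1, keepdims=True)
        alpha = np.exp(e)
        alpha /= alpha.sum(axis=1, keepdims=True)
        self._x, self._s, self._alpha = x, s, alpha
        return (alpha[:, :, None] * x).sum(axis=1)  # (B, C)

    def backward(self, dctx):
        x, s, alpha = self._x, self._s, self._alpha
        B, L, C = x.shape
        dx = alpha[:, :, None] * dctx[:, None, :]
        dalpha = np.einsum("bc,blc->bl", dctx, x)
        de = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        self.dv[...] = np.einsum("bla,bl->a", s, de)
        ds = de[:, :, None] * self.v
        du = ds * (1 - s * s)                       # (B, L, a)
        self.dWa[...] = np.einsum("blc,bla->ca", x, du)
        self.dba[...] = du.sum(axis=(0, 1))
        dx += du @ self.Wa.T
        return dx
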