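"""RR estimators: the dilated residual CNN and simplified reference baselines.

The core regressor stacks *RespBlocks*: residual units in which the input
runs through three parallel ("horizontal") dilated convolutions, each
deepened by a second identical dilated convolution (the "vertical" layer),
and the branch outputs are summed together with a channel-mean shortcut of
the block input. Each block is followed by a strided downsampling
convolution and average pooling, with the filter count doubling per stage;
a global-average-pooling head with two dense layers emits the RR in brpm.

The seven structural hyperparameters live in :class:`DilatedResNetConfig`
with the selected values as defaults and the search ranges enforced as
invariants. All estimators share the :class:`Estimator` contract
(deterministic ``predict`` given fixed weights, a ``fit`` hook, portable
checkpoints) so training and evaluation code never special-cases a model.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .errors import ConfigurationError, ShapeError
from .nn import (
    AdditiveAttention,
    AvgPool1D,
    BiLSTM,
    Dense,
    DilatedConv1D,
    GlobalAvgPool1D,
    LSTM,
    Layer,
    ReLU,
    Sequential,
    StridedConv1D,
    Upsample1D,
)

__all__ = [
    "DilatedResNetConfig",
    "RespBlock",
    "resp_block",
    "Estimator",
    "NeuralEstimator",
    "MeanPredictor",
    "build_dilated_resnet",
    "build_baseline",
    "load_estimator",
    "BASELINE_NAMES",
    "HYPERPARAM_RANGES",
]

# Search ranges of the seven structural hyperparameters (inclusive bounds).
HYPERPARAM_RANGES = {
    "n_blk": (1, 5),
    "kernel_blk": (2, 5),
    "d_blk": (1, 5),
    "kernel_dwn": (2, 4),
    "filters_c": (4, 10),
    "s_c": (2, 4),
    "n_den": (20, 100),
}


@dataclass(frozen=True)
class DilatedResNetConfig:
    """Structural hyperparameters; defaults are the selected optimum."""

    n_blk: int = 4
    kernel_blk: int = 2
    d_blk: int = 3
    kernel_dwn: int = 3
    filters_c: int = 8
    s_c: int = 2
    n_den: int = 86
    input_len: int = 1800
    input_channels: int = 1
    vertical_mode: str = "per_branch"  # or "post_sum"

    def validate(self) -> None:
        for name, (lo, hi) in HYPERPARAM_RANGES.items():
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and lo <= v <= hi):
                raise ConfigurationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.input_len < 1 or self.input_channels < 1:
            raise ConfigurationError("input_len and input_channels must be >= 1")
        if self.vertical_mode not in ("per_branch", "post_sum"):
            raise ConfigurationError("vertical_mode must be 'per_branch' or 'post_sum'")

    @property
    def stage_filters(self) -> List[int]:
        base = 2**self.filters_c
        return [base * 2**s for s in range(self.n_blk)]

    def to_dict(self) -> Dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "DilatedResNetConfig":
        return cls(**d)


class RespBlock(Layer):
    """Residual unit: 3 parallel dilated-conv branches + channel-mean shortcut.

    ``per_branch`` mode stacks the second ("vertical") dilated convolution
    inside each branch; ``post_sum`` applies one vertical convolution to the
    sum of the horizontal branch outputs. With all convolution weights at
    zero the block reduces exactly to the broadcast channel-mean of its
    input, which is the residual-path contract tests rely on.
    """

    N_BRANCHES = 3

    def __init__(self, cin: int, filters: int, kernel: int, dilation: int,
                 rng: Optional[np.random.Generator] = None,
                 vertical_mode: str = "per_branch", dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.name = f"respblock_{cin}x{filters}"
        self.cin, self.filters = cin, filters
        self.vertical_mode = vertical_mode
        self.branches: List[Sequential] = []
        for i in range(self.N_BRANCHES):
            layers = [DilatedConv1D(cin, filters, kernel, dilation, rng, dtype), ReLU()]
            if vertical_mode == "per_branch":
                layers += [DilatedConv1D(filters, filters, kernel, dilation, rng, dtype), ReLU()]
            self.branches.append(Sequential(layers, name=f"branch{i}"))
        self.post: Optional[Sequential] = None
        if vertical_mode == "post_sum":
            self.post = Sequential(
                [DilatedConv1D(filters, filters, kernel, dilation, rng, dtype), ReLU()],
                name="vertical",
            )

    @property
    def parameters(self):
        ps = [p for b in self.branches for p in b.parameters]
        if self.post is not None:
            ps += self.post.parameters
        return ps

    @property
    def gradients(self):
        gs = [g for b in self.branches for g in b.gradients]
        if self.post is not None:
            gs += self.post.gradients
        return gs

    def forward(self, x, train=False):
        if x.ndim != 3 or x.shape[2] != self.cin:
            raise ShapeError(f"{self.name}: expected (B, L, {self.cin}), got {x.shape}")
        shortcut = x.mean(axis=2, keepdims=True)  # broadcast channel mean
        branch_sum = self.branches[0].forward(x, train=train)
        for b in self.branches[1:]:
            branch_sum = branch_sum + b.forward(x, train=train)
        if self.post is not None:
            branch_sum = self.post.forward(branch_sum, train=train)
        return branch_sum + shortcut

    def backward(self, dy):
        dbranch = self.post.backward(dy) if self.post is not None else dy
        dx = self.branches[0].backward(dbranch)
        for b in self.branches[1:]:
            dx = dx + b.backward(dbranch)
        # shortcut: d(mean over cin channels), broadcast-added over filters
        dx += np.repeat(dy.sum(axis=2, keepdims=True) / self.cin, self.cin, axis=2)
        return dx


def resp_block(features: np.ndarray, cfg: DilatedResNetConfig,
               cin: Optional[int] = None, filters: Optional[int] = None,
               seed: int = 0) -> np.ndarray:
    """Functional convenience: apply a freshly initialized RespBlock."""
    cfg.validate()
    x = np.asarray(features)
    cin = cin if cin is not None else x.shape[2]
    filters = filters if filters is not None else 2**cfg.filters_c
    block = RespBlock(cin, filters, cfg.kernel_blk, cfg.d_blk,
                      np.random.default_rng(seed), cfg.vertical_mode)
    return block.forward(x)


class Estimator:
    """Uniform interface over every RR regressor."""

    name: str = "estimator"

    @property
    def parameters(self) -> List[np.ndarray]:
        return []

    @property
    def gradients(self) -> List[np.ndarray]:
        return []

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> None:
        raise NotImplementedError

    def predict(self, windows, batch_size: int = 256) -> np.ndarray:
        """RR estimates (brpm) for a sequence of windows or an (N, L) array."""
        X = windows_to_array(windows)
        out = np.empty(X.shape[0], dtype=float)
        for i in range(0, X.shape[0], batch_size):
            out[i : i + batch_size] = self.forward(X[i : i + batch_size]).ravel()
        return out

    def fit(self, train_windows, val_windows, cfg=None):
        from .training import TrainConfig, train

        return train(self, train_windows, val_windows, cfg or TrainConfig())

    def save(self, path) -> Path:
        raise NotImplementedError


def windows_to_array(windows) -> np.ndarray:
    """Stack WindowSamples (or accept a 2/3-D array) into (N, L, 1) float32."""
    if isinstance(windows, np.ndarray):
        X = windows
    else:
        X = np.stack([np.asarray(w.values) for w in windows])
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[:, :, None]
    if X.ndim != 3:
        raise ShapeError(f"expected (N, L) or (N, L, C) windows, got {X.shape}")
    return X


class NeuralEstimator(Estimator):
    """An Estimator backed by a Sequential network mapping (B, L, C) -> (B, 1)."""

    def __init__(self, network: Sequential, name: str, meta: Optional[Dict] = None):
        self.network = network
        self.name = name
        self.meta = meta or {}

    @property
    def parameters(self):
        return self.network.parameters

    @property
    def gradients(self):
        return self.network.gradients

    def forward(self, X, train=False):
        return self.network.forward(X, train=train)

    def backward(self, dy):
        self.network.backward(dy)

    def summary(self) -> List[Dict]:
        """Per-layer name/output-shape/parameter-count table (runs a forward)."""
        in_len = int(self.meta.get("input_len", 64))
        in_ch = int(self.meta.get("input_channels", 1))
        x = np.zeros((1, in_len, in_ch), dtype=np.float32)
        rows = []
        for layer in self.network.layers:
            x = layer.forward(x)
            rows.append(
                {"layer": layer.name, "output_shape": list(x.shape), "params": layer.n_params()}
            )
        rows.append({"layer": "total", "output_shape": list(x.shape),
                     "params": int(sum(r["params"] for r in rows))})
        return rows

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2)

    def save(self, path) -> Path:
        p = Path(path)
        p.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"param_{i}": a for i, a in enumerate(self.parameters)}
        np.savez(p, meta=json.dumps({"name": self.name, **self.meta}), **arrays)
        return p

    def load_weights(self, path) -> "NeuralEstimator":
        with np.load(path, allow_pickle=False) as npz:
            for i, p in enumerate(self.parameters):
                arr = npz[f"param_{i}"]
                if arr.shape != p.shape:
                    raise ConfigurationError(
                        f"checkpoint parameter {i} has shape {arr.shape}, expected {p.shape}"
                    )
                p[...] = arr
        return self


class MeanPredictor(Estimator):
    """Predicts a constant (the training-set mean RR); the no-skill reference."""

    def __init__(self, mean_rr: float = 0.0):
        self.name = "train_mean"
        self.mean_rr = float(mean_rr)

    def forward(self, X, train=False):
        return np.full((X.shape[0], 1), self.mean_rr, dtype=np.float32)

    def backward(self, dy):
        pass

    def fit(self, train_windows, val_windows=None, cfg=None):
        self.mean_rr = float(np.mean([w.rr_true for w in train_windows]))
        return self, None


def _simulate_lengths(cfg: DilatedResNetConfig) -> List[int]:
    L = cfg.input_len
    lengths = []
    for _ in range(cfg.n_blk):
        L = -(-L // 2)          # strided downsampling conv, ceil(L/2)
        L = L // cfg.s_c        # average pooling
        lengths.append(L)
    return lengths


def _min_admissible_len(cfg: DilatedResNetConfig) -> int:
    lo, hi = 1, 1
    while True:
        probe = DilatedResNetConfig(**{**cfg.to_dict(), "input_len": hi})
        if min(_simulate_lengths(probe)) >= 1:
            break
        hi *= 2
    while lo < hi:
        mid = (lo + hi) // 2
        probe = DilatedResNetConfig(**{**cfg.to_dict(), "input_len": mid})
        if min(_simulate_lengths(probe)) >= 1:
            hi = mid
        else:
            lo = mid + 1
    return lo


def build_dilated_resnet(cfg: DilatedResNetConfig = DilatedResNetConfig(),
                         seed: int = 0, dtype=np.float32) -> NeuralEstimator:
    """Build the dilated residual RR regressor for a given configuration."""
    cfg.validate()
    if min(_simulate_lengths(cfg)) < 1:
        raise ConfigurationError(
            f"input_len={cfg.input_len} does not survive {cfg.n_blk} downsampling "
            f"stages; minimum admissible length is {_min_admissible_len(cfg)}"
        )
    rng = np.random.default_rng(seed)
    layers: List[Layer] = []
    cin = cfg.input_channels
    for filters in cfg.stage_filters:
        layers.append(RespBlock(cin, filters, cfg.kernel_blk, cfg.d_blk, rng,
                                cfg.vertical_mode, dtype))
        layers.append(StridedConv1D(filters, filters, cfg.kernel_dwn, 2, rng, dtype))
        layers.append(ReLU())
        layers.append(AvgPool1D(cfg.s_c))
        cin = filters
    layers.append(GlobalAvgPool1D())
    layers.append(Dense(cin, cfg.n_den, rng, dtype))
    layers.append(ReLU())
    layers.append(Dense(cfg.n_den, 1, rng, dtype))
    meta = {"kind": "dilated_resnet", "config": cfg.to_dict(),
            "input_len": cfg.input_len, "input_channels": cfg.input_channels,
            "seed": seed}
    return NeuralEstimator(Sequential(layers, name="dilated_resnet"),
                           name="dilated_resnet", meta=meta)


class _UNetRegressor(Layer):
    """Small 1-D encoder/decoder with skip concatenations (B, L, C) -> (B, L', F)."""

    name = "unet_core"

    def __init__(self, cin: int, base: int, rng: np.random.Generator, dtype=np.float32):
        self.enc1 = Sequential([DilatedConv1D(cin, base, 3, 1, rng, dtype), ReLU()], "enc1")
        self.pool1 = AvgPool1D(2)
        self.enc2 = Sequential([DilatedConv1D(base, 2 * base, 3, 1, rng, dtype), ReLU()], "enc2")
        self.pool2 = AvgPool1D(2)
        self.bott = Sequential([DilatedConv1D(2 * base, 4 * base, 3, 1, rng, dtype), ReLU()], "bott")
        self.up2 = Upsample1D(2)
        self.dec2 = Sequential([DilatedConv1D(6 * base, 2 * base, 3, 1, rng, dtype), ReLU()], "dec2")
        self.up1 = Upsample1D(2)
        self.dec1 = Sequential([DilatedConv1D(3 * base, base, 3, 1, rng, dtype), ReLU()], "dec1")
        self.base = base
        self._subs = [self.enc1, self.enc2, self.bott, self.dec2, self.dec1]

    @property
    def parameters(self):
        return [p for s in self._subs for p in s.parameters]

    @property
    def gradients(self):
        return [g for s in self._subs for g in s.gradients]

    @staticmethod
    def _match(a: np.ndarray, b: np.ndarray):
        L = min(a.shape[1], b.shape[1])
        return a[:, :L, :], b[:, :L, :], L

    def forward(self, x, train=False):
        e1 = self.enc1.forward(x, train=train)
        e2 = self.enc2.forward(self.pool1.forward(e1), train=train)
        z = self.bott.forward(self.pool2.forward(e2), train=train)
        u2full = self.up2.forward(z)
        u2, s2, L2 = self._match(u2full, e2)
        self._l2 = (L2, u2full.shape[1], e2.shape[1])
        d2 = self.dec2.forward(np.concatenate([u2, s2], axis=2), train=train)
        u1full = self.up1.forward(d2)
        u1, s1, L1 = self._match(u1full, e1)
        self._l1 = (L1, u1full.shape[1], e1.shape[1])
        d1 = self.dec1.forward(np.concatenate([u1, s1], axis=2), train=train)
        return d1

    @staticmethod
    def _pad_len(d: np.ndarray, L_full: int):
        if d.shape[1] == L_full:
            return d
        return np.pad(d, ((0, 0), (0, L_full - d.shape[1]), (0, 0)))

    def backward(self, dy):
        b = self.base
        dcat1 = self.dec1.backward(dy)
        L1, Lu1, Le1 = self._l1
        du1 = self._pad_len(dcat1[:, :, : 2 * b], Lu1)
        ds1 = self._pad_len(dcat1[:, :, 2 * b :], Le1)
        dd2 = self.up1.backward(du1)
        dcat2 = self.dec2.backward(dd2)
        L2, Lu2, Le2 = self._l2
        du2 = self._pad_len(dcat2[:, :, : 4 * b], Lu2)
        ds2 = self._pad_len(dcat2[:, :, 4 * b :], Le2)
        dz = self.up2.backward(du2)
        de2 = self.pool2.backward(self.bott.backward(dz)) + ds2
        de1 = self.pool1.backward(self.enc2.backward(de2)) + ds1
        return self.enc1.backward(de1)


BASELINE_NAMES = ("resnet", "lstm", "cnn_lstm", "bilstm", "attn_bilstm", "unet_regressor")

# Recurrent widths of the reference LSTM-family baselines.
BASELINE_UNITS = {"lstm": 256, "cnn_lstm": 256, "bilstm": 128, "attn_bilstm": 64}


class _ResidualDownBlock(Layer):
    """Conv/stride-2 block with a pooled 1x1-projection shortcut."""

    def __init__(self, cin: int, cout: int, rng, dtype=np.float32):
        self.name = f"resblock_{cin}x{cout}"
        self.main = Sequential(
            [StridedConv1D(cin, cout, 3, 2, rng, dtype), ReLU(),
             DilatedConv1D(cout, cout, 3, 1, rng, dtype)],
            "main",
        )
        self.proj = StridedConv1D(cin, cout, 1, 2, rng, dtype)
        self.out_relu = ReLU()

    @property
    def parameters(self):
        return self.main.parameters + self.proj.parameters

    @property
    def gradients(self):
        return self.main.gradients + self.proj.gradients

    def forward(self, x, train=False):
        y = self.main.forward(x, train=train) + self.proj.forward(x, train=train)
        return self.out_relu.forward(y, train=train)

    def backward(self, dy):
        dy = self.out_relu.backward(dy)
        return self.main.backward(dy) + self.proj.backward(dy)


def build_baseline(name: str, cfg: Optional[Dict] = None, seed: int = 0,
                   dtype=np.float32) -> NeuralEstimator:
    """Build a simplified reference baseline honoring the Estimator contract.

    ``resnet`` stacks five residual downsampling conv blocks; the LSTM
    family uses recurrent widths 256 (vanilla), 256 (cnn_lstm), 128 per
    direction (bilstm) and 64 per direction (attn_bilstm); the U-Net
    regressor ends in a dense scalar head. These are reduced stand-ins
    that preserve each family's architectural idea, not re-implementations
    of the third-party originals.
    """
    cfg = dict(cfg or {})
    if name not in BASELINE_NAMES:
        raise ConfigurationError(
            f"unknown baseline '{name}'; choices: {', '.join(BASELINE_NAMES)}"
        )
    rng = np.random.default_rng(seed)
    cin = int(cfg.get("input_channels", 1))
    input_len = int(cfg.get("input_len", 1800))
    layers: List[Layer]
    if name == "resnet":
        filters = cfg.get("filters", (32, 64, 64, 128, 128))
        layers = []
        c = cin
        for f in filters:
            layers.append(_ResidualDownBlock(c, f, rng, dtype))
            c = f
        layers += [GlobalAvgPool1D(), Dense(c, 32, rng, dtype), ReLU(), Dense(32, 1, rng, dtype)]
    elif name == "lstm":
        u = int(cfg.get("units", BASELINE_UNITS["lstm"]))
        layers = [LSTM(cin, u, False, rng, dtype), Dense(u, 1, rng, dtype)]
    elif name == "cnn_lstm":
        u = int(cfg.get("units", BASELINE_UNITS["cnn_lstm"]))
        f = int(cfg.get("filters", 16))
        layers = [
            StridedConv1D(cin, f, 5, 4, rng, dtype), ReLU(), AvgPool1D(2),
            LSTM(f, u, False, rng, dtype), Dense(u, 1, rng, dtype),
        ]
    elif name == "bilstm":
        u = int(cfg.get("units", BASELINE_UNITS["bilstm"]))
        layers = [BiLSTM(cin, u, False, rng, dtype), Dense(2 * u, 1, rng, dtype)]
    elif name == "attn_bilstm":
        u = int(cfg.get("units", BASELINE_UNITS["attn_bilstm"]))
        layers = [
            BiLSTM(cin, u, True, rng, dtype),
            AdditiveAttention(2 * u, int(cfg.get("att_dim", 32)), rng, dtype),
            Dense(2 * u, 1, rng, dtype),
        ]
    else:  # unet_regressor
        base = int(cfg.get("base_filters", 16))
        layers = [
            _UNetRegressor(cin, base, rng, dtype),
            GlobalAvgPool1D(),
            Dense(base, int(cfg.get("n_den", 32)), rng, dtype), ReLU(),
            Dense(int(cfg.get("n_den", 32)), 1, rng, dtype),
        ]
    meta = {"kind": "baseline", "baseline": name, "config": cfg,
            "input_len": input_len, "input_channels": cin, "seed": seed}
    return NeuralEstimator(Sequential(layers, name=name), name=name, meta=meta)


def load_estimator(path) -> NeuralEstimator:
    """Rebuild an estimator from a checkpoint written by ``save``."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"checkpoint not found: {p}")
    try:
        with np.load(p, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
    except (OSError, ValueError, KeyError) as exc:
        raise ConfigurationError(f"unreadable checkpoint {p}: {exc}") from exc
    if meta.get("kind") == "dilated_resnet":
        est = build_dilated_resnet(DilatedResNetConfig.from_dict(meta["config"]),
                                   seed=meta.get("seed", 0))
    elif meta.get("kind") == "baseline":
        est = build_baseline(meta["baseline"], meta.get("config"), seed=meta.get("seed", 0))
    else:
        raise ConfigurationError(f"checkpoint {p} has unknown kind {meta.get('kind')!r}")
    return est.load_weights(p)
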