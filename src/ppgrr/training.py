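"""Subject-wise cross-validated training with Adam, plateau LR and early stop.

Protocol integrity is enforced, not assumed: ``train`` refuses to run if any
subject contributes windows to both the train and validation sets, and
``make_subject_folds`` builds a true partition of subject IDs. The training
loss is mean absolute error on brpm — the same quantity that is reported —
and the estimator returned is the best-validation checkpoint, not the last
epoch.

The learning-rate schedule multiplies the rate by ``plateau_factor`` (0.1)
whenever the validation loss fails to improve for ``plateau_patience``
epochs; training halts after ``early_stop_patience`` epochs without a new
best validation loss, or at ``max_epochs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import LeakageError, ParameterError, SplitError
from .model import Estimator, windows_to_array
from .nn import Adam
from .preprocess import WindowSample, assign_group
from .records import PPGRecord, record_mean_rr

__all__ = [
    "FoldSplit",
    "TrainConfig",
    "TrainingHistory",
    "make_subject_folds",
    "split_test_by_group",
    "train",
    "windows_for_subjects",
]


@dataclass(frozen=True)
class FoldSplit:
    """Subject-disjoint train/validation ID partition for one CV fold."""

    fold_index: int
    train_ids: frozenset
    val_ids: frozenset

    def __post_init__(self):
        if self.train_ids & self.val_ids:
            raise LeakageError(
                f"fold {self.fold_index}: subjects in both train and val: "
                f"{sorted(self.train_ids & self.val_ids)}"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer schedule; defaults follow the training protocol."""

    batch_size: int = 256
    lr0: float = 1e-3
    max_epochs: int = 1000
    plateau_factor: float = 0.1
    plateau_patience: int = 10
    plateau_threshold: float = 1e-3
    early_stop_patience: int = 50
    seed: int = 0
    shuffle: bool = True
    verbose: bool = False

    def validate(self) -> None:
        if not (0 < self.plateau_factor < 1):
            raise ParameterError("plateau_factor must be in (0, 1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ParameterError("patience values must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ParameterError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainingHistory:
    epoch: List[int] = field(default_factory=list)
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    lr: List[float] = field(default_factory=list)
    best_epoch: int = 0
    best_val_loss: float = float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": self.epoch, "train_loss": self.train_loss,
             "val_loss": self.val_loss, "lr": self.lr}
        )


def make_subject_folds(ids: Sequence[str], k: int = 5, seed: int = 0) -> List[FoldSplit]:
    """Shuffle subject IDs and partition them into k near-equal validation sets."""
    unique = sorted(set(map(str, ids)))
    if len(unique) < k:
        raise SplitError(f"need at least k={k} subjects, got {len(unique)}")
    rng = np.random.default_rng(seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    val_sets = np.array_split(np.array(order, dtype=object), k)
    folds = []
    for i, val in enumerate(val_sets):
        val_ids = frozenset(map(str, val))
        folds.append(FoldSplit(i, frozenset(unique) - val_ids, val_ids))
    return folds


def split_test_by_group(
    records: Sequence[PPGRecord],
    n_per_group: Dict[str, int],
    seed: int = 0,
) -> Tuple[List[PPGRecord], List[PPGRecord]]:
    """Withdraw per-group subject counts into a test set (subject group = group
    of the record's mean RR); remaining records form the training pool."""
    rng = np.random.default_rng(seed)
    by_group: Dict[str, List[int]] = {"slow": [], "normal": [], "rapid": []}
    for i, rec in enumerate(records):
        by_group[assign_group(record_mean_rr(rec))].append(i)
    test_idx: Set[int] = set()
    for group, want in n_per_group.items():
        if group not in by_group:
            raise SplitError(f"unknown breathing group '{group}'")
        pool = by_group[group]
        if want > len(pool):
            raise SplitError(
                f"group '{group}': requested {want} test subjects but only "
                f"{len(pool)} available"
            )
        if want > 0:
            test_idx.update(rng.choice(pool, size=want, replace=False).tolist())
    train = [r for i, r in enumerate(records) if i not in test_idx]
    test = [r for i, r in enumerate(records) if i in test_idx]
    return train, test


def windows_for_subjects(windows: Sequence[WindowSample], ids) -> List[WindowSample]:
    ids = set(map(str, ids))
    return [w for w in windows if w.subject_id in ids]


def _check_no_leakage(train_windows, val_windows) -> None:
    train_ids = {w.subject_id for w in train_windows}
    val_ids = {w.subject_id for w in val_windows}
    common = train_ids & val_ids
    if common:
        raise LeakageError(f"subjects in both train and validation: {sorted(common)}")


def train(
    estimator: Estimator,
    train_windows: Sequence[WindowSample],
    val_windows: Sequence[WindowSample],
    cfg: TrainConfig = TrainConfig(),
) -> Tuple[Estimator, TrainingHistory]:
    """Train an estimator with MAE loss; returns the best-validation checkpoint.

    Subject leakage between the two sets is a hard protocol violation. The
    history records per-epoch train/val loss and the learning rate actually
    in force, so schedule behaviour is auditable after the fact.
    """
    cfg.validate()
    _check_no_leakage(train_windows, val_windows)
    X = windows_to_array(train_windows)
    y = np.array([w.rr_true for w in train_windows], dtype=np.float32)
    Xv = windows_to_array(val_windows)
    yv = np.array([w.rr_true for w in val_windows], dtype=float)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(estimator.parameters, lr=cfg.lr0)
    history = TrainingHistory()
    best_params = [p.copy() for p in estimator.parameters]
    lr = cfg.lr0
    plateau_wait = 0
    stop_wait = 0
    n = X.shape[0]
    for epoch in range(1, cfg.max_epochs + 1):
        idx = rng.permutation(n) if cfg.shuffle else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            sel = idx[start : start + cfg.batch_size]
            xb, yb = X[sel], y[sel]
            pred = estimator.forward(xb, train=True).ravel()
            resid = pred - yb
            epoch_loss += float(np.abs(resid).sum())
            dy = (np.sign(resid) / sel.size).astype(np.float32)[:, None]
            estimator.backward(dy)
            opt.lr = lr
            opt.step(estimator.gradients)
        train_loss = epoch_loss / n
        val_pred = estimator.predict(Xv, batch_size=cfg.batch_size)
        val_loss = float(np.mean(np.abs(val_pred - yv)))
        history.epoch.append(epoch)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.lr.append(lr)
        if cfg.verbose:
            print(f"epoch {epoch:4d}  train {train_loss:.4f}  val {val_loss:.4f}  lr {lr:g}")
        if val_loss < history.best_val_loss - cfg.plateau_threshold:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_params = [p.copy() for p in estimator.parameters]
            plateau_wait = 0
            stop_wait = 0
        else:
            if val_loss < history.best_val_loss:
                # still keep the strictly-best weights even below threshold
                history.best_val_loss = val_loss
                history.best_epoch = epoch
                best_params = [p.copy() for p in estimator.parameters]
            plateau_wait += 1
            stop_wait += 1
            if stop_wait >= cfg.early_stop_patience:
                break
            if plateau_wait >= cfg.plateau_patience:
                lr *= cfg.plateau_factor
                plateau_wait = 0
    for p, bp in zip(estimator.parameters, best_params):
        p[...] = bp
    return estimator, history
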