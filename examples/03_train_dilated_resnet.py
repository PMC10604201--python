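"""Train a small dilated residual network on synthetic windows (~2 min on CPU).

Builds a 12-subject cohort spanning all three breathing groups, preprocesses
it at a reduced 5 Hz window rate, holds out one subject-wise fold, and
trains a width-reduced network with the standard schedule (Adam, MAE loss,
plateau learning-rate decay, early stopping).
"""

import numpy as np

from ppgrr import (
    DilatedResNetConfig,
    TrainConfig,
    build_dilated_resnet,
    mae,
    make_cohort,
    make_subject_folds,
    slice_windows,
    train,
)
from ppgrr.model import MeanPredictor
from ppgrr.preprocess import WindowSpec
from ppgrr.training import windows_for_subjects

records = make_cohort(12, (0.25, 0.5, 0.25), duration_s=144.0, fs=125.0, seed=1)
wspec = WindowSpec(target_fs=5.0)
windows = [w for r in records for w in slice_windows(r, wspec)]
folds = make_subject_folds([w.subject_id for w in windows], k=4, seed=1)
tr = windows_for_subjects(windows, folds[0].train_ids)
va = windows_for_subjects(windows, folds[0].val_ids)
print(f"{len(tr)} training / {len(va)} validation windows, subject-disjoint")

est = build_dilated_resnet(
    DilatedResNetConfig(filters_c=5, n_blk=3, input_len=tr[0].values.size), seed=1
)
cfg = TrainConfig(batch_size=128, max_epochs=60, plateau_patience=5,
                  early_stop_patience=10, seed=1)
est, hist = train(est, tr, va, cfg)

yv = np.array([w.rr_true for w in va])
mp = MeanPredictor()
mp.fit(tr)
print(f"best validation MAE: {hist.best_val_loss:.3f} brpm (epoch {hist.best_epoch})")
print(f"held-out MAE:        {mae(yv, est.predict(va)):.3f} brpm")
print(f"train-mean baseline: {mae(yv, mp.predict(va)):.3f} brpm")
print("\nThe network should land well under the no-skill baseline: on clean")
print("synthetic data the band-passed window is nearly a sinusoid at RR/60 Hz.")
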