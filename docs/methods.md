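# Methods

## Problem and signal model

The target is the respiratory rate (RR, breaths per minute) of a monitored
adult, estimated continuously from the finger photoplethysmogram (PPG)
alone. Respiration modulates the PPG through three mechanisms: an additive
low-frequency baseline wander (intrathoracic pressure coupling), amplitude
modulation of the cardiac pulse (stroke-volume variation), and frequency
modulation of the heart period (respiratory sinus arrhythmia). The
estimator never demodulates these explicitly; it regresses RR directly
from one minute of respiratory-band PPG.

## Preprocessing chain

Order of operations per record: FIR band-pass at the source rate → 60 s /
1 s-shift slicing → linear-interpolation resampling → per-window min–max
normalization → RR labeling over the same half-open interval.

* **Band-pass 0.1–0.4 Hz, Hamming-window FIR, 1025 taps at 125 Hz.** The
  band covers 6–24 brpm, the range where most adult breathing sits. The
  tap count is the smallest power-of-two-plus-one that satisfies the
  response contract this package enforces at design time: no more than
  3 dB of droop over the passband interior (edges pulled in 0.05 Hz) and
  at least 20 dB of attenuation from 1 Hz up (measured: ≈ −2.4 dB at
  0.15/0.35 Hz, 0.0 dB at 0.25 Hz, < −50 dB at 1 Hz). Rates above
  24 brpm have an attenuated fundamental; per-window renormalization
  restores the waveform as long as the residual dominates in-band noise,
  which holds for the synthetic generator and is a known limitation on
  noisy clinical data.
* **Zero-phase application.** The filter is applied forward–backward
  (reflect padding, convolution with the tap autocorrelation), so breath
  timing is not delayed relative to the RR labels. A causal filter would
  shift the signal by ~4 s at 1025 taps, misaligning labels near window
  edges.
* **Half-open windows `[start, start+60)`** prevent an exhalation mark on
  a window boundary from being counted twice.
* **Per-window normalization.** Min–max scope is the window, not the
  dataset, so inference on a new subject never depends on training-set
  statistics. RR labels stay in brpm; `normalize_labels_minmax` exists to
  probe the alternative reading (targets scaled to [0, 1]) but is off by
  default.
* **Label derivation.** A 1 Hz RR series labels a window with its
  arithmetic mean over the window (median available for heavy-tailed
  references); event references (breath annotations, exhalation marks)
  use count × 60/width. Records whose reference is entirely missing are
  rejected at read time; partially missing 1 Hz samples are linearly
  interpolated with a warning.
* **Exclusion hook.** Published window counts for the clinic-collected
  dataset imply exclusion rules that are not recoverable from any
  description; `slice_windows` therefore exposes a per-window exclusion
  hook and bakes in no guessed rule.

## The synthetic generator

`generate_ppg` builds
`(1 + a_am·sin 2πf_r t) · pulse(φ(t)) + a_bw·sin(2πf_r t + ψ) + ε(t)` with
`φ'(t) = (hr/60)(1 + a_fm·sin 2πf_r t)` and a fixed two-Gaussian
systolic/diastolic pulse template. Defaults (wander 30 % of pulse
amplitude, AM 20 %, FM 5 %, white noise SD 0.01) sit in the range reported
for real finger PPG. Cohorts draw subject RR uniformly per breathing group
(slow 6–11.5, normal 12–20, rapid 20.5–35 brpm) and HR uniformly on
55–110 bpm, with mild per-subject jitter of the modulation depths; group
proportions use largest-remainder rounding so a cohort's composition is a
deterministic function of the mix.

What it does *not* emulate: arrhythmia, dicrotic-notch morphology
variants, probe-coupling transients, or disease/intervention effects on
the waveform. Passing tests on this generator demonstrate that the
pipeline and model recover a breathing rate that is genuinely present in
the band-passed signal; they do not certify clinical accuracy.

A note on mechanisms: a *purely* frequency-modulated pulse train carries
no energy inside 0.1–0.4 Hz (FM creates sidebands around the cardiac
harmonics), so the FM pathway is verified by demodulating the
instantaneous heart period rather than by a band-passed periodogram. This
is the standard way RSA-based RR estimators read FM and reflects real
physics, not a generator defect.

**SNR injection.** Artifacts are sums of eight sinusoids with frequencies
drawn uniformly from 0.05–1 Hz — deliberately overlapping the respiratory
band so robustness tests are a real stressor — scaled in closed form so
that `10·log10(P_signal/P_artifact)` on mean-removed signals hits the
target exactly (round-trip error is at floating-point level, well inside
the 0.1 dB verification band). SNR is defined on mean-removed power; the
injection happens on the raw record before the standard pipeline runs.

## Model

A *RespBlock* sends its input through three parallel ("horizontal")
dilated convolutions (kernel `kernel_blk` = 2, dilation `d_blk` = 3,
ReLU), each deepened by a second identical ("vertical") convolution, and
sums the branch outputs with a channel-mean shortcut of the block input
broadcast across filters. Summation (not concatenation) keeps the
residual reading; with all weights at zero the block is exactly the
broadcast channel mean, which tests pin down. Two open wiring choices are
flag-switchable: the vertical layer per branch (default) or applied once
to the branch sum (`vertical_mode="post_sum"`).

The network stacks `n_blk` = 4 such stages; each stage's block is followed
by a stride-2 convolution (kernel `kernel_dwn` = 3) and average pooling of
stride `s_c` = 2 — the only reading that uses both downsampling
hyperparameters — with filters doubling per stage from `2^filters_c` = 256.
The head is global average pooling → dense(`n_den` = 86, ReLU) →
dense(1), emitting brpm directly. The stage count is configurable because
the block count and the number of compression iterations are described
inconsistently in prose; the selected-value table (4 blocks) is taken as
authoritative. Geometry is validated at build time: an input too short to
survive the downsampling stack raises an error naming the minimum
admissible length.

Weights are He-initialized from a seeded generator with zero biases, so
builds, forward passes and training runs are bit-reproducible; the
forward pass is pure (no dropout/batch-norm state).

Baselines (`resnet`, `lstm`, `cnn_lstm`, `bilstm`, `attn_bilstm`,
`unet_regressor`) are *simplified reference implementations* that preserve
each family's architectural idea at the stated recurrent widths
(256/256/128/64) and end in a scalar dense head; they satisfy the same
Estimator contract and are not re-implementations of the third-party
originals.

All layers are numpy with hand-written backprop, each verified against
central finite differences in float64 (`tests/test_nn_layers.py`).

## Training protocol

MAE on brpm is both the loss and the reported metric — no surrogate.
Adam starts at 1e-3, batch 256. Subject-wise k-fold: IDs are shuffled
once (seeded) and partitioned into near-equal validation sets;
`train` re-checks disjointness of the actual window sets and refuses to
run on leakage. On a validation plateau the learning rate is multiplied
by 0.1 — the plateau step is read as a *reduction*; an increase would
contradict its stated purpose of more precise learning. Plateau patience
10, early-stop patience 50 and improvement threshold 1e-3 are this
package's choices (no published values exist); both patiences are
configurable and the scaled-down runs use tighter ones (5/12). The best
validation checkpoint is restored before returning, so the returned
model's validation MAE never exceeds any epoch's.

## Hyperparameter search

The seven structural hyperparameters live in integer boxes
(1–5, 2–5, 1–5, 2–4, 4–10, 2–4, 20–100). Backends: `random` (uniform
draws) and `smbo` (seeded random exploration, then greedy ±1 coordinate
moves around the incumbent with random restarts). On unimodal objectives
the sequential backend recovers the exact optimum within ~200 evaluations
on the ~5·10⁵-point grid; uniform random search cannot (the hit
probability of 200 draws is ~4·10⁻⁴), which is why the optimum-recovery
test runs against the sequential backend. A failing objective scores
+inf and the search continues.

## Evaluation conventions

* MAE ± SD: SD across folds for cross-validation tables, across windows
  for single-run test tables; both are computed and labeled.
* Bland–Altman: bias = mean(est − true), limits = bias ± 1.96·SD(diff),
  sample SD.
* Pearson r: two-sided p; undefined (reported as absent) when either side
  is constant.
* Box-plot outliers: absolute errors outside the 1.5·IQR whiskers
  (quartiles by linear interpolation); the rule is stated because
  published box plots rarely state theirs.
* An empty breathing group is reported as absent, never as zero error.
* SNR tables carry an `original` row (no injection); a +inf level is an
  exact no-op and reproduces it.

## Problem sizes for the desk-scale runs

The parameter-recovery run (tests and acceptance script) uses 24 subjects
(6 slow / 12 normal / 6 rapid), 144 s records → 2040 windows, windows
resampled to 5 Hz (300 samples — the respiratory band ends below 0.6 Hz,
so 5 Hz sampling is lossless for this task), a width-reduced network
(`filters_c` = 5, `n_blk` = 3), at most 200 epochs with early stopping.
These sizes are the package's choice of a single-CPU desk-scale
experiment; at them the run converges in ~20–30 epochs to a held-out MAE
around 0.2–0.4 brpm, versus ~3–5 brpm for the train-mean predictor, and
the SNR-robustness table degrades monotonically from 20 dB to 10 dB in
expectation over ten artifact seeds.

## Known limitations

* No signal-quality index or artifact rejection: every window is used.
* Rates above ~24 brpm rely on the renormalized residual of an attenuated
  fundamental; on low-SNR clinical data this is the regime that degrades
  first.
* The LSTM-family baselines loop over time in Python; they are reference
  implementations for short windows, not production recurrents.
* Published per-dataset error tables from clinical recordings are not
  reproducible without those recordings; the harness regenerates their
  layouts and protocol, not their numbers.
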