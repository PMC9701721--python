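# Methods

`preictal` implements a patient-specific seizure-prediction pipeline: it
classifies 1-second EEG segments as **pre-ictal** (the horizon before a
seizure, 30 min by default) or **inter-ictal** (baseline between seizures),
using a parallel CNN+LSTM network — the *multi-frame* network — over a dual
representation of each segment.  This note documents the model, the choices
made where the design was genuinely open, the synthetic study conditions,
and the limits of what the tests demonstrate.

## Labeling and preprocessing

Given a recording with seizure annotations:

1. Seizures separated by less than 30 min are merged into one event.
2. The window `[onset − 30 min, onset)` of each merged seizure is
   pre-ictal, truncated at the recording start or at the previous exclusion
   zone.
3. The ictal span plus a post-ictal buffer (default 30 min, configurable)
   is excluded from both classes; everything else is inter-ictal.  The
   clinical datasets this mirrors do not state a post-ictal rule; the
   symmetric 30-min buffer is this package's default, chosen so post-ictal
   recovery cannot contaminate the inter-ictal class.
4. The signal is bandpass filtered (zero-phase Butterworth, default
   0.5–70 Hz, order 4 — the standard clinical EEG band under the 128 Hz
   Nyquist of the common target rate; band and order are unstated upstream
   and configurable here), resampled to 256 Hz (polyphase), and cut into
   non-overlapping 1-s segments of shape `(N, M)` with `M = fs`.
5. Class balance: inter-ictal segments are randomly subsampled, without
   replacement and seeded, down to the pre-ictal count.

## The dual segment representation

Each retained segment is presented to the network twice:

* **Instance view** — a `(2, N, N)` tensor.
  Plane 0 is the PCA score matrix: the N channels are the observations and
  the M time samples the features; features are mean-centered across
  observations and the observations are projected onto the first N
  principal axes (SVD).  Rows are electrodes, columns are components in
  decreasing explained-variance order.  With N observations the centered
  matrix has rank ≤ N−1, so the trailing component(s) are zero columns.
  PCA is fitted **per segment** (the only reading consistent with a
  per-segment `(N, M) → (N, N)` transform).  Each component's sign is fixed
  so its largest-magnitude loading is positive, making the plane
  deterministic across linear-algebra backends.
  Plane 1 is the Pearson channel-correlation matrix
  `R[i,j] = corr(x_i, x_j)`: symmetric, unit diagonal, entries in [−1, 1].
  Pairs involving a zero-variance (flat-lined) channel get correlation 0 —
  not NaN — so the tensor stays finite.
* **Sequence view** — the raw `(N, M)` matrix read column-by-column: a
  length-M time series of N-dimensional samples, in increasing time order.

Whether the raw view should be standardized at preprocessing time is left
off by default (an open choice upstream); instead the **training procedure**
standardizes inputs with statistics fitted on each fold's training split
only (per-channel mean/sd for the raw view, per-plane scalar mean/sd for
the tensor), applied identically to validation and test data.  EEG
amplitudes sit on an arbitrary microvolt scale, and first-layer saturation
otherwise prevents the recurrent branch from training; fitting on the
training split keeps folds leakage-free.

## The four architectures

All four models consume the same batch object and end in the same fully
connected head: Dense(128)+ReLU+Dropout(0.5) → Dense(64)+ReLU+Dropout(0.5)
→ Dense(2)+softmax, dropout active only in training.

* **CNN (instance-based)** — three blocks of [conv → batch-norm → ReLU] on
  the `(2, N, N)` tensor, 2×2 max-pooling after blocks 1 and 2 only, then
  flatten.  The conv filter counts/kernels are not fully pinned down by the
  source architecture diagram; the defaults here are a conventional
  LeNet/AlexNet-style schedule — 3×3 kernels, stride 1, same padding,
  filters (32, 64, 128) — and every one of these is a `ModelSpec` field, so
  other readings are a config edit away.  Batch-norm sits between the
  convolution and the ReLU, matching the listed block order.
* **LSTM (sequence-based)** — a single LSTM layer (256 cells by default)
  over the sequence view; the feature is the final-time-step hidden state.
* **Multi-frame** — both branches run in parallel on the same segment; the
  flattened CNN feature and the 256-dim LSTM feature are concatenated
  before the head (e.g. 2048 + 256 = 2304 for N = 16 defaults).
* **CNN-LSTM (sequential baseline)** — the same conv trunk; its pre-flatten
  feature map `(C, h, w)` is unrolled along the width into a length-`w`
  sequence of `C·h`-dim vectors fed to the LSTM, then the head.  The
  sequential wiring is under-specified in the source; this reading is used
  because it hands the LSTM a genuine (spatial) sequence rather than a
  single vector.

The networks are implemented directly on numpy (`preictal.nn`): conv via
shifted-view einsum, batch-norm with running statistics, max-pool with
floor semantics on odd extents, a full BPTT LSTM (forget-gate bias 1,
orthogonal recurrent init), inverted dropout, Adam.  Every backward pass is
gradient-checked against central finite differences in float64; training
runs in float32.

## Training and evaluation

The loss is the binary cross-entropy `−[y log p + (1−y) log(1−p)]`
(probabilities clipped to `[1e−7, 1−1e−7]`), minimized with Adam.  The
reference setting is batch 512 and learning rate 3e-4; the batch size is
auto-capped at the training-set size so small runs remain valid.  Epoch
budget and stopping are not specified upstream: training runs up to
`max_epochs` (default 50) with early stopping on validation loss
(patience 5) and best-checkpoint restore.

Evaluation is leave-one-seizure-out cross-validation, requiring at least
three seizures.  With K pre-ictal blocks, fold k tests all segments of
pre-ictal block k plus the k-th inter-ictal block; the balanced
inter-ictal segments carry no natural one-to-one pairing with seizures, so
they are partitioned into K contiguous-in-time chunks and chunk k is paired
with pre-ictal block k (a documented interpretation).  The remaining
segments are split 80 %/20 % into train/validation at the segment level,
stratified by class, seeded.  Per fold, confusion counts at threshold 0.5
on the pre-ictal probability (ties count as positive) yield accuracy,
sensitivity (= recall), specificity, precision and F1; AUC is the
trapezoidal area under the empirical ROC.  Degenerate denominators yield a
defined 0 with a warning flag.  AUC is computed per fold and then averaged
(not pooled), matching the per-experiment-then-mean protocol; the subject
report is the arithmetic mean over folds.  The ablation runs this whole
procedure per architecture per seed and tabulates mean ± sd and pairwise
deltas.

Everything is a pure function of (data, spec, config, seed): weight
initialization, dropout masks, shuffling and fold splits are all seeded,
and re-runs are bit-identical.

## The synthetic study conditions

The generator (`preictal.synthio`) emulates exactly the two statistical
axes the two branches are designed to detect, with a single global effect
size δ:

* signal = channel-correlated AR(1) noise + band-limited oscillation
  packets (theta 4–8, alpha 8–13, beta 13–30 Hz), mixed through the
  Cholesky factor of an equicorrelation matrix — the simplest model with a
  controllable spectrum *and* a controllable cross-channel correlation;
* **correlation shift**: the equicorrelation level rises by `δ · corr_shift`
  (default 0.3) in pre-ictal — the instance-branch signature;
* **spectral shift**: a fraction `δ · spectral_shift` (default 0.9) of
  alpha-band oscillatory power moves out of alpha in pre-ictal, most of it
  (`slow_wave_fraction`, default 0.85) into theta — emulating pre-ictal
  slowing — and the rest into beta: the sequence-branch signature.

δ = 0 makes the regimes identical by construction (both shifts scale with
δ).  Oscillations are emitted as 2-s tapered packets, each drawing fresh
per-channel frequencies and phases, so every labeled block exercises the
full band rather than keeping one idiosyncratic frequency; without this,
block-level frequency quirks dominate block-held-out generalization.  The
AR(1) noise floor takes `noise_fraction` (default 0.2) of the per-channel
variance.  Amplitudes are microvolt-like (sd 30) and arbitrary; the
pipeline is scale-invariant where it must be (the correlation plane) and
input standardization absorbs scale elsewhere.  A 20-s, 3 Hz high-amplitude
discharge is generated per seizure purely so the labeling rules have
something to exclude.

The default effect sizes are deliberately **large**.  Desk-scale subjects
provide minutes of data per class where clinical studies use hours, so the
per-segment effect is scaled up until a simple reference classifier — a
logistic regression on Welch band powers and the mean off-diagonal
correlation — separates the regimes with AUC ≥ 0.95 under
block-held-out folds.  That calibration was done with the oracle, not with
the networks.  A genuinely subtle spectral effect is also the wrong test
target here: a final-hidden-state LSTM trained on a few hundred segments
memorizes before it learns band-power-like statistics (the pure
mixture-weight version of the task is near-unlearnable at this data scale
even when a band-power oracle scores 0.99), which is why the programmed
spectral change is a strong, theta-biased slowing rather than a symmetric
reshuffle.

What the generator does **not** emulate: 1/f spectra fitted to real EEG,
artifacts (eye-blink, EMG, electrode pops), non-stationary drift within a
regime, montage effects, or inter-subject variability.  Passing tests
therefore demonstrate that the implementation is correct and that the two
branches detect the feature modes they were designed for — not that the
architecture reaches any particular performance on clinical EEG.

### Desk-scale problem sizes

The shipped tests and `scripts/acceptance.py` use subjects of 4 seizures
with 2-min pre-ictal and 5-min inter-ictal blocks — 960 balanced segments —
at 8 channels / 64 Hz for the ablation studies and 16 channels / 256 Hz for
the full-rate signal-recovery run, with slimmed networks (conv filters
8/16/32, 64 LSTM cells) and Adam at 3e-3, batch 64, up to 60 epochs with
patience 12 (30/6 where both effects are strong).  These sizes keep a full
four-way, multi-seed ablation within desk CPU time while leaving every
tested property intact; the architecture defaults remain the reference
ones (filters 32/64/128, 256 LSTM cells, batch 512, lr 3e-4).

## Numerical choices

* float32 parameters and activations for training; float64 for gradient
  checks and the representation planes.
* Cross-entropy clipping `ε = 1e−7`; batch-norm `ε = 1e−5`, momentum 0.9;
  Adam (0.9, 0.999, 1e−8).
* Zero-variance channels in the correlation plane → 0; channels are
  "flat-lined" when their centered norm is below `1e−10·√M·max|x|`.
* PCA components beyond the numerical rank are zero-filled; ties in
  max-pooling route the gradient to the first maximum.
* Equicorrelation targets are validated for positive definiteness
  (`−1/(N−1) < ρ < 1`) before Cholesky.
* EDF export quantizes to 16 bits over a per-channel symmetric range; the
  round-trip error is bounded by `range/65535`.
* HDF5 archives are written without modification timestamps so identical
  runs produce byte-identical files.

## Known limitations

* The recurrent branch needs either strong spectral effects or much more
  data than a desk-scale subject provides; its clinical-scale behavior is
  not characterized here.
* The inter-ictal-block-to-seizure pairing rule for folds is an
  interpretation; other pairings (e.g. random) would change fold
  composition for subjects with irregular inter-ictal structure.
* Multi-file subjects are stitched assuming contiguity when start times
  are unavailable; gaps become excluded time only if annotated as such.
* The CLI and library evaluate segment classification only; event-based
  seizure-prediction metrics (false-prediction rate per hour, prediction
  horizon analysis) are out of scope.
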