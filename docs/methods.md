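# Methods note

This note records the modeling assumptions, parameter choices and numerical
decisions behind `topofnirs`, and what the synthetic-data experiments do and
do not demonstrate.

## Preprocessing

Raw data are optical-density changes ΔOD at two wavelengths per optode. The
modified Beer–Lambert law inverts them sample-wise to concentration
changes: `[ΔHbO; ΔHbR] = E⁻¹ · [ΔOD(λ1); ΔOD(λ2)] / (d·l)` with `E` the 2×2
extinction matrix (defaults for 760/850 nm, in 1/(mM·cm)), `d` the
differential pathlength factor (default 6.0) and `l` the source–detector
separation (default 3.0 cm). A near-singular `E` is rejected rather than
inverted, since the species are then not separable.

Filtering is zero-phase Butterworth (forward–backward, second-order
sections), order 3, default band 0.01–0.1 Hz; zero-phase application avoids
shifting the sluggish hemodynamic response in time. Optional downsampling
uses polyphase resampling with line-extension padding (constant signals
stay constant at the edges). Resampling, when requested, precedes
filtering, so the filter runs at the lower rate. Each annotated task window
(default 10 s) is cut into non-overlapping 1 s epochs that inherit the
trial's label; a trailing partial segment is dropped by default. Epochs are
baseline-corrected by subtracting the per-channel mean of the 1 s
pre-stimulus interval of their parent trial.

## Connectivity features

All features operate on the preprocessed epoch, per HbO/HbR channel pair:

- **Connection strength** `s = (ρ + 1)/2`, where ρ is the Pearson
  correlation of the pair over the whole epoch. `s ∈ [0, 1]`; strong
  anticorrelation (the physiological HbO/HbR signature) maps near 0.
- **Connection density** `Sd`: the fraction of sliding windows (length 1 s,
  stride 1 sample) whose within-window correlation exceeds 0.3.
- **RFSMD** `= 1 / (mean|x − x′| + ε)`, ε = 1e-6: reciprocal of the mean
  absolute sample-wise difference between the two channels.
- **Global efficiency** of the binary graph over all `C` channels with
  edges where the inter-channel correlation exceeds 0.3: the mean inverse
  shortest-path length over ordered node pairs (unweighted BFS;
  disconnected pairs contribute 0).

Thresholds compare the signed correlation by default
(`FeatureConfig.thresholds_signed`); absolute-value thresholding is a
config switch, relevant when anticorrelated structure should count as
connectivity. The fused vector is `f3 = [f1; f2; e]` with `f1` the raw
epoch flattened time-major, `f2` the `(s, Sd, RFSMD)` triples in pair
order, and `e` the efficiency; `D = C·T + 3·Cp + 1`.

Degenerate epochs (zero variance in a channel) yield correlation 0 with an
explicit flag rather than NaN propagation.

## Model

See the README for the architecture. Decisions worth recording:

- The Transformer encodes **along time within each pair**, with weights
  shared across pairs; the Bi-LSTM then runs **across the pair sequence**.
  The pair axis is the recurrent axis because the attention weights α are
  per-pair quantities and gate the recurrent integration of pair evidence.
- α enters every LSTM gate input. Default `alpha_mode="scalar_per_step"`
  appends step `i`'s own α_i to that step's gate input; `"full_vector"`
  appends the whole α vector to every step. The scalar mode is the default
  because it keeps the gate input size independent of `Cp`.
- The classifier consumes the **final** Bi-LSTM state (concatenated
  directions) by default; `lstm_output="mean_pooled"` is available.
- Encoder blocks are post-LN; positional encoding is sinusoidal; dropout is
  inverted (applied at train time only: 0.1 on the fused projection, 0.2 in
  the MLP).
- Training: Adam (lr 1e-3, decoupled-from-schedule classic L2 weight decay
  1e-4), batch 5, up to 200 epochs, an inner stratified 80/20 validation
  split driving a plateau scheduler (factor 0.5, patience 10, floor 1e-5)
  and best-validation checkpointing. `val_fraction <= 0` validates on the
  training set itself (used by the memorization check).
- Everything is seeded: parameter init, batch order, dropout, fold
  assignment. Per-(subject, fold) seeds are derived as
  `seed + 1000·subject + fold`.

The autodiff engine is a tape-based reverse-mode Tensor on NumPy arrays
(matmul with broadcasting, elementwise ops, reductions, indexing, softmax,
log-softmax with detached max-shift for stability). Its gradients are
verified against central finite differences in the test suite; the model's
end-to-end gradients are spot-checked the same way.

## Synthetic data generator

The generator emulates a blocked motor-imagery protocol: per subject, a
shuffled balanced sequence of trials (10 s task, 15 s rest) at 10 Hz over
`Cp` HbO/HbR channel pairs.

- **Task response**: boxcar convolved with a double-gamma HRF (modes 6 s
  and 16 s, undershoot ratio 1/6), peak-normalized to 1 so
  `task_amplitude` is the evoked peak amplitude in concentration units.
- **Connectivity**: each class has a `Cp×Cp` latent correlation template
  (Cholesky-sampled) and per-pair HbO–HbR coupling coefficients `c_i`. HbO
  receives the latent `u`; HbR is `hbr_scale · (amp·r + c_i·u +
  √(1−c_i²)·v)` with `hbr_scale = −0.3`, giving inverted, scaled HbR and
  tunable within-pair coupling.
- The latent is smoothed with a short moving average (0.3 s, variance
  restored) rather than the HRF: an HRF-smoothed latent has roughly one
  effective degree of freedom inside a 1 s epoch, which would make
  within-epoch correlation estimates meaningless. The smoothing length is
  a generator parameter.
- **Noise**: white noise plus linear drift, 0.1 Hz Mayer waves, 0.3 Hz
  respiration and 1 Hz cardiac components with randomized phases.
- Non-positive-semidefinite templates are rejected at configuration time.
- `two_class_block_config` plants disjoint coupled half-blocks with
  identical task amplitudes across classes, so the class signal lives in
  the covariance structure only. `shuffle_epoch_labels` produces the null
  control by permuting labels per subject at the epoch level — the unit of
  classification — so a correct decoder's accuracy is binomial around
  chance. (Trial-level shuffling would leave the ten epochs of a trial
  identically labeled, inflating the variance of pooled accuracy far
  beyond binomial.)

## Evaluation

Accuracy is `100·trace/total` of the confusion matrix. Cohen's kappa uses
the standard multi-class marginal-agreement form. ROC curves sweep the
class-score threshold one-vs-rest with tied scores grouped; trapezoidal
AUC equals the Mann–Whitney pair-counting statistic with ties counted ½
(asserted in tests). Classes absent from a test fold are reported as
skipped rather than given fabricated AUCs. Protocols: stratified
subject-specific 5-fold and leave-one-subject-out. Feature-group
comparisons use Welch's t (two groups) or one-way ANOVA (more), with
optional Benjamini–Hochberg correction.

## Problem sizes in the test suite

The dataset and model sizes used by the tests are the package's own
choices, set before the corresponding checks were first run and sized for
a single-CPU budget: the connectivity-recovery benchmark uses 2 subjects ×
2 classes × 10 trials × 10 epochs = 400 one-second epochs over 10 pairs,
a reduced-width model (`d_model` 16, hidden sizes 16–32) and a 30-epoch
training budget; the ablation benchmark uses 8 pairs, one subject and 5
seeds.

## What the experiments show — and don't

The synthetic experiments are *correctness and sensitivity* checks: they
show the pipeline recovers planted connectivity structure well above
chance, collapses to chance under epoch-level label permutation, and that
the explicit graph features carry most of the signal when classes differ
only in covariance. They are not evidence about real fNIRS data: the
generator's noise model is simplified (no motion artifacts, no superficial
systemic contamination, stationary coupling within trials), channel
geometry is abstract (no optode montage or short-separation channels), and
effect sizes were chosen to be detectable at small problem sizes.
Hyperparameter defaults follow common practice and were not tuned per
dataset.

## Other limitations

- The NumPy autodiff engine is single-threaded and unoptimized; it is
  adequate for the problem sizes above, not for large-scale training.
- Only two-wavelength MBLL is supported; no scattering or partial-volume
  corrections.
- The BFS efficiency treats the graph as unweighted; weighted efficiency
  is out of scope.
- HDF5 artifacts disable timestamp tracking so identical config + seed
  yields byte-identical files; this is required for the manifest's
  hash-based reproducibility guarantee.
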