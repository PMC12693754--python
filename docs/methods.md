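# Methods

## Scope

`mdfnet` implements an EEG classification pipeline for Parkinson's disease
(PD) vs. healthy controls (HC): synthetic cohort generation, preprocessing,
three-domain feature extraction, the multi-domain fusion network, its
training regimen, and subject-level evaluation. This note records the model
assumptions, the tunable parameters, and the decisions taken where the
protocol leaves the design open.

## Synthetic cohort generator

Real resting-state PD/HC cohorts are rarely shareable, so the package ships
a generative stand-in whose *statistical* structure matches what the
analysis assumes. Each subject's recording is built from `n_sources = 8`
latent sources mixed into 32 channels:

* each source is a sum of band-limited Gaussian oscillations in the
  canonical EEG bands — delta 1–4, theta 4–8, alpha 8–13, beta 13–30 Hz —
  over a `1/f` background (power exponent 1.0). Band-limited noise is white
  noise passed through a 4th-order zero-phase Butterworth band-pass and
  normalized to unit variance;
* baseline band amplitudes are (delta, theta, alpha, beta) =
  (1.0, 0.9, 1.1, 0.7) with per-subject log-normal jitter (σ = 0.15) and
  additional per-source jitter (σ = 0.10) — individual variability on a
  common rhythm profile;
* the mixing matrix is **cohort-shared** with a 20 % per-subject Gaussian
  perturbation. Scalp topography is largely common across subjects (same
  cap layout, broadly similar head geometry); making the topography fully
  subject-specific would put an unrealistically high-dimensional nuisance
  between training and held-out subjects;
* per-channel sensor noise (1 % of signal scale) and a ×10 scaling put the
  signals on a microvolt scale.

**Class contrast.** The PD class multiplies its delta and theta amplitudes
by `1 + 0.3 · effect_size`. The effect sits on *relative* low-frequency
power, not absolute amplitude, so per-channel z-scoring cannot erase it.
`effect_size` is dimensionless; the default 1.0 gives a moderately separable
cohort (neither trivial nor hopeless for the end-to-end pipeline), while the
end-to-end smoke benchmark uses 6.0 ("strongly separable": subject-level
delta+theta relative-power distributions no longer overlap).

**Demographics** are drawn per class to match the emulated study population:
age HC ~ N(55.8, 9.2²), PD ~ N(63.8, 7.5²) years (clipped to 18–95); male
proportion 145/289 (HC) and 71/126 (PD); Hoehn–Yahr stage for PD only,
rounded N(1.9, 0.8²) clipped to 1–5.

**Artifacts** (optional, `rate` events/minute, Poisson): blink-like smooth
biphasic 0.3-s transients (120–220 µV) loaded on the frontal electrodes, and
broadband 0.4-s high-kurtosis bursts (20–100 Hz, 40–80 µV) on a random
channel group — the two artifact classes an ICA step is expected to remove.

All randomness flows from one integer seed through `numpy` `SeedSequence`
spawning; identical specs give bit-identical cohorts.

What the generator does **not** emulate: volume-conduction head modelling,
realistic PD electrophysiology beyond the band-power contrast (no
beta-burst dynamics, no tremor artifacts), non-stationarity across the
recording, eye-open/closed state changes, electrode drift. Passing tests on
this cohort demonstrate that the pipeline recovers a planted low-frequency
class contrast under realistic mixing and noise — not clinical performance.

## Preprocessing

Fixed stage order: band-pass → ICA → resample → z-score → segment.

* **Band-pass** 1–40 Hz, zero-phase (forward-backward) Butterworth of order
  5. The order is chosen so a 50 Hz mains tone is attenuated by more than
  20 dB while a 10 Hz tone stays within 5 % of unit gain.
* **ICA**: FastICA with 15 components and seeded initialisation. Component
  scores are (a) back-projected variance `‖A_k‖²·var(s_k)` and (b) source
  kurtosis; a component is removed when either score *strictly exceeds* the
  90th percentile of its 15 per-recording scores (union of both flags).
  With 15 components this flags 2 per criterion before overlap, giving the
  expected 2–4 removals per recording. The cleaned signal is the input
  minus the back-projection of the flagged components only, so an empty
  flag set is exactly the identity (PCA truncation residue is never
  discarded). Non-convergence degrades to a logged pass-through.
* **Resampling** to 20 Hz by polyphase filtering (`scipy.signal.
  resample_poly`), which anti-alias filters at the new Nyquist; only
  down-sampling is supported.
* **Z-scoring** per channel over the whole recording, population σ
  (ddof = 0), applied before segmentation (the stage order fixes the
  normalization scope). Zero-variance channels become all-zero with a
  warning.
* **Segmentation** into non-overlapping `window_s` windows (default 1 s →
  N = 20 samples), trailing remainder discarded. Non-overlapping windows
  avoid train/validation leakage between a subject's overlapping segments.

## Domain features

Per segment: raw time matrix [C×N]; one-sided FFT amplitude spectrum
`|X(k)|` for k = 0..⌊N/2⌋ (raw DFT magnitude, no 1/N factor, no dB
scaling) giving 11 bins at N = 20; single-level db4 DWT under *symmetric*
signal extension, concatenated `[cA ‖ cD]`, giving ⌊(20+8−1)/2⌋ = 13
coefficients per band, 26 total. Symmetric extension is the choice that
produces exactly these published feature counts. The frequency and wavelet
branches consume the z-scored segments (pipeline order), not raw-amplitude
ones.

## Network

* **Temporal branch (TTCN)**: 3 residual blocks with output channels
  (64, 128, 64), kernel 3, stride 1, dilations (1, 2, 4) (`d_i = 2^{i−1}`),
  GELU activations, dropout 0.2 after each block. The dilated convolution is
  causal (left padding only). `R(x)` is a 1×1 convolution whenever the
  channel count changes. A learnable channel-attention gate on the raw
  32-channel input (softmax over channels of a learned time-scoring vector,
  rescaled by C to preserve signal scale) supplies the 32-length channel
  attention map reported by the attention analysis — the printed equations
  define attention only over time and coefficients, neither of length 32,
  so this gate is the package's design choice for producing that map.
  Temporal attention pooling collapses time.
* **Cmix branches** (frequency, wavelet): 1×1 input projection 32 → 64,
  then three stages at channel widths (64, 128, 64); each stage is a
  residual token mix across the coefficient axis (`W_token`, F×F) followed
  by a residual channel mix (`W_channel`, C×C), with 1×1 projections where
  the width changes. The mixing weights are realised as kernel-size-1
  convolutions along the mixed axis, satisfying both the matrix-product and
  the "1-D convolution" readings. Attention pooling over coefficients.
* **Fusion**: concatenation of the enabled branches' pooled 64-d vectors
  (192-d for T+F+W) into a single linear layer → 2 logits. This is the
  simplest head consistent with the symmetric branch widths; branch toggles
  (`branches_enabled`) give the ablation configurations.
* **Loss**: cross-entropy on label-smoothed targets (ε = 0.1) with class
  weights (w_HC, w_PD) = (0.8, 1.2) — the 1.2 attaches to PD, the minority
  positive class — reduced as the weighted mean over the batch.

**Initialisation.** Glorot-scale Gaussian init for convolutions and mixing
weights; the attention scoring vectors and the fusion head use a small init
(σ = 0.01). The residual mixer stack grows activation magnitudes roughly
linearly with depth, and at Glorot scale the attention softmaxes and the
output softmax start saturated (confident-wrong logits, collapse to a
constant class); the small head init starts training at near-uniform
attention and near-zero logits while leaving every parameter a nonzero
gradient path.

**Autodiff.** All of the above runs in float64 NumPy on a small
reverse-mode engine (`mdfnet.autodiff`) providing exactly the needed
operator set. Gradients are validated against central finite differences
(worst relative error ~1e-7 across all parameters) and the layer forward
passes against brute-force loop oracles at 1e-9.

## Training regimen

AdamW (β₁ = 0.9, β₂ = 0.99, ε = 1e-8) with decoupled weight decay 0.01 (the
"L2 regularization 0.01" is read as decoupled decay, the AdamW-native
form). Full-protocol schedule: 500 epochs, batch 512 — linear warm-up
1e-9 → 1e-5 over epochs 0–99, plateau at 1e-5 for epochs 100–299, then
*geometric* (log-linear) decay to 1e-7 across epochs 300–499; "gradual
decay" is unspecified in shape, and a geometric ramp spans the two orders
of magnitude evenly and is continuous at both joins. Validation F1 is
computed at sample level each epoch (subject-level voting is reserved for
evaluation); the snapshot with the highest value is kept, ties resolved to
the earliest epoch. Data order is reshuffled each epoch from a per-epoch
derived seed; no early stopping.

`TrainConfig.scaled(epochs, lr_peak)` produces the desk-scale variant: the
1:2:2 phase split is preserved and the floor/final rates scale with the
peak. The full regimen moves the Adam iterate O(1) in parameter distance
(~120 k steps × 1e-5); a 50-epoch smoke run has ~700 steps, so its peak is
raised to 1e-3 to cover a comparable distance. This scaled schedule is the
package's smoke-benchmark configuration, not a claim about the full
regimen's optima.

## Evaluation protocol

* **Balanced subject-independent folds**: among `n_trials` (default 1000)
  seeded class-stratified round-robin partitions, pick the one minimising
  `1e4·(max−min PD per fold) + 1e2·std(fold mean ages) + 1·std(fold male
  proportions)` — lexicographic-like weights encoding the priority order
  class balance ≫ age balance ≫ sex balance.
* **Majority voting**: per-segment PD calls at threshold 0.5 (boundary to
  PD); tied votes resolved by mean PD probability ≥ 0.5. The mean
  probability also serves as the subject-level AUC score — consistent with
  the tie rule's use of averaged probability, since no subject-level score
  is otherwise defined.
* **Metrics**: confusion counts with PD positive; accuracy, precision,
  recall, F1 from the counts; AUC by rank statistic
  (`sklearn.roc_auc_score`, cross-checked against pair counting). Per-fold
  reports, their arithmetic mean, and the pooled subject-level confusion
  matrix are all emitted (fold means and pooled counts are different
  conventions; both are labelled rather than reconciled). Single-class
  inputs flag AUC as undefined instead of failing.
* **Paired t-tests** on per-fold metrics via `scipy.stats.ttest_rel`;
  all-zero differences return (t = 0, p = 1), constant nonzero differences
  return (±inf, 0) with a warning.
* **Repeated hold-out**: stratified 60/20/20 subject splits, n runs; mean,
  SD, and a normal-approximation 95 % CI (1.96·SD/√n).
* **Sweeps** re-run preprocessing + CV per (window, rate) setting.
* **Attention summaries** average the per-segment channel / frequency-bin /
  wavelet-coefficient attention vectors over a segment set; averages of
  simplex vectors remain on the simplex.

## Problem sizes in the test suite

Unit tests run on 12-subject cohorts with 15–30 s recordings at 125–250 Hz
and 3-epoch training smokes. The end-to-end benchmark uses 40 subjects
(20/20), 60-s recordings at the native 500 Hz, effect size 6.0, and the
50-epoch scaled schedule (batch 128, peak LR 1e-3); on one CPU it finishes
in minutes and reaches subject-level accuracy above 0.85 with voting
dominating sample-level accuracy. These sizes are the package's smoke-scale
choices; the protocol itself is size-agnostic.

## Known limitations

* The synthetic cohort's class signal is stationary and purely spectral;
  architectures exploiting temporal dynamics have no advantage over
  spectral ones on it.
* FastICA on statistically near-Gaussian band-limited sources separates
  artifacts well but brain-source unmixing is only approximate; the
  variance/kurtosis percentile rule always removes the top-scoring
  components, artifact or not, mirroring the fixed-percentile protocol.
* The NumPy implementation is single-threaded BLAS-bound; it is sized for
  desk-scale cohorts, not for 415-subject × 5-min studies.
* EDF export quantizes to 16 bits with per-channel physical scaling
  (relative error ≤ 2⁻¹⁵ of each channel's peak).
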