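# Methods

## The classification problem

A resting multi-lead electrocardiogram records the heart's electrical
activity from twelve electrode projections (leads I, II, III, aVR, aVL,
aVF, V1–V6).  Arrhythmias and ischemia-type abnormalities express
themselves jointly in *time* (QRS width, RR-interval statistics, ST/T
morphology) and in *space* (which leads see the abnormality: inferior
infarcts project onto II/III/aVF, lateral ST/T changes onto V3–V6).
`ecgcoattn` classifies whole recordings, shaped `(batch, 1, leads, time)`,
into diagnostic labels — multi-label superclasses
(NORM/MI/STTC/CD/HYP-style) or mutually exclusive rhythm categories —
with a convolutional network whose gating mechanisms attend to leads and
time jointly.

## Network

The body is fully convolutional with stride 1 and symmetric "same" zero
padding on both axes; no spatial downsampling occurs before global average
pooling, which absorbs all resolution at the head.

1. **Stem**: one (3 leads × 15 samples) convolution, batch norm, ReLU,
   dropout.  The tall-and-wide kernel mixes neighbouring leads with a long
   time window from the first layer.
2. **Two lead–temporal co-attention residual (LTCAR) blocks** with rising
   channel counts.  Each block is a pre-activation residual unit
   (BN → ReLU before the paths) with two parallel paths:
   * *Lead path*: a (k × n) convolution spanning k neighbouring leads,
     gated by **spatial attention** — channel-wise max and mean maps are
     stacked as two channels, passed through a single 7×7 convolution and
     a sigmoid, and the resulting per-position weights in (0, 1) rescale
     the map over the lead × time plane.  Feature-map (whole-channel)
     dropout follows, so the model cannot rely on any single filter.
   * *Temporal path*: m = 2 stacked (1 × n) convolutions confined to
     single leads, each with BN + ReLU, gated by **channel attention** —
     squeeze-and-excitation weights from global average pooling through a
     bottleneck of reduction r, then a sigmoid.
   The two paths are summed and added to the identity skip (1×1-projected
   when channel counts change).  The sum-merge is a deliberate choice:
   the residual convention treats parallel paths as additive refinements
   of the identity.
3. **Three multi-scale branches** with temporal widths n = 5, 7, 15:
   LTCAR(3, n) → 1×1 conv + BN + ReLU → LTCAR(1, n).  Short kernels catch
   QRS-scale detail, the 15-wide kernel covers P–QRS–T context.  Branch
   outputs are concatenated along channels.
4. **Head**: global average pooling → Linear → BN → GELU → dropout →
   Linear, emitting raw logits (sigmoid for multi-label scoring, softmax
   for exclusive tasks).

Which attention operator sits on which path is bound *by mechanism*
(spatial gate on the lead path, channel gate on the temporal path);
`ModelConfig.swap_attention` exposes the transposed binding for
comparison.  Ablation switches disable either gate, replace LTCAR blocks
with plain convolutions (`use_ltcar=False`), or keep only the middle
branch (`n_branches=1`).

### Channel plan and parameter calibration

The default configuration uses stem 64, LTCAR 128/256, branch 320,
head 1024, r = 16, m = 2, giving 25.3M trainable parameters — within ±25%
of the 24.585M scale of the published full-size model this architecture
follows.  Exact widths are not determined by that reference, so the
parameter count is a calibration band, not an exactness claim; a halved
plan (32/64/128/160/512) lands near 6.3M and is therefore *not* the
default.  All widths are overridable.

## Training protocol

* **He initialization** (normal, variance 2/fan-in) for convolutions and
  linear maps; zero biases; unit batch-norm scales.
* **Focal loss**: per-label binary form
  `−α_t (1−p_t)^γ log p_t` with `p = sigmoid(logit)` for multi-label
  tasks; softmax form on the true class for exclusive tasks.  Defaults
  γ = 2.0, α = 0.25 — the standard published values; the loss reduces to
  α-weighted cross-entropy at γ = 0 (a tested identity).
* **AdamW** (lr₀ 1e-3 default, weight decay 1e-2, decay skipped on biases
  and norm parameters) with a **per-step cosine annealing** schedule from
  lr₀ to lr_min = 1e-6.
* **Gradient clipping** by global L2 norm at threshold 10.0.
* **On-the-fly augmentation** of training folds only; validation and test
  records are never transformed (asserted by test).
* The checkpoint returned is the epoch with the best validation macro AUC.

Training is bit-reproducible on a fixed-thread run: one seed fans out via
a seed sequence to data order, dropout, and augmentation streams.

## Augmentations

Record-level: circular time shift (≤0.5 s), amplitude scaling
(0.9–1.1), additive Gaussian noise (sd 0.02 in scaled units).  QRS-aware
(for beat-segmented data with known R peaks): noise confined to ±0.05 s
QRS windows, per-lead gain (0.9–1.1), and a piecewise-linear monotone time
warp with four interior knots whose slope stays within 1 ± warp_max
(warp_max 0.1), guaranteeing strict monotonicity and an argmax
displacement bounded by warp_max·T.  Magnitudes are package defaults
chosen to be slight and label-preserving; each transform applies
independently with probability 0.5.

## Preprocessing

* **Robust scaling** per record and per lead: `(x − median) / IQR`,
  quantiles by linear interpolation between order statistics; a zero-IQR
  (constant) lead is centred only.  Lead-wise statistics make the
  normalization robust to transient artifacts confined to single leads.
* **Length unification**: truncate to, or zero-pad up to, the target
  length (10 s at the record sampling rate).
* **QRS detection**: the classical Pan–Tompkins cascade — 5–15 Hz
  band-pass (2nd-order Butterworth, zero-phase), 5-point derivative,
  squaring, 0.150 s moving-window integration, adaptive dual thresholds
  with running signal/noise peak estimates (0.125 blending), a 0.200 s
  refractory period, and search-back at 1.66× the running mean RR.  Each
  detection is refined to the local signal maximum within ±0.05 s — this
  refinement is this package's interpretation of an "improved" detector;
  the published classic gives no such step.  Detection runs on lead II by
  default, where the synthetic projection places the strongest R wave.
* **Beat segmentation**: a fixed window from 0.4 s before to 0.6 s after
  each R peak (one full cardiac cycle at resting rates); windows that
  leave the record are dropped; segments inherit the record's labels.
* **WFDB reading**: a self-contained header/format-16 reader keeps the
  real-data on-ramp dependency-free; leads found among the standard 12
  are reordered canonically.  Scope is deliberately narrow (single-file
  format-16 records, the format used by the public 100 Hz resting-ECG
  exports); other WFDB formats are out of scope.

## Synthetic data: what it emulates and what it does not

Each record is a train of template beats.  A beat is five Gaussian bumps
(P, Q, R, S, T) with physiologic default offsets/widths/amplitudes; the
single reference waveform is projected to 12 leads by a fixed weight
vector (lead II strongest, aVR inverted) with ±8% per-record jitter,
giving the inter-lead correlation structure lead attention can exploit.
Class identity enters through controlled edits:

| class | edit |
|---|---|
| MI | ST depression + deep Q on II, III, aVF |
| STTC | ST elevation + T inversion on V3–V6 |
| CD | QRS widths × 1.8 |
| HYP | R × 1.8, S × 1.5 |
| bradycardia | mean RR 1.2 s |
| tachycardia | mean RR 0.5 s |
| irregular rhythms | RR jitter sd ≥ 0.15 s |

Two regimes mirror the public benchmarks the pipeline targets:
record-level multi-label at 100 Hz / 10 s with an official-style
10-fold split (folds 1–8 train, 9 validation, 10 test), and exclusive
rhythm classes at 500 Hz with known R-peak positions and a five-fold
split.  Fold assignment is label-stratified round-robin.  Additive
Gaussian noise (default sd 0.05 mV) is the only noise model.

Ground truth is stored per record: exact R-peak indices and, for
ischemia-type classes, the injected-anomaly region (lead subset × per-beat
ST/T windows), enabling exact detector scoring and class-activation
localization checks.

*Limitations*: no baseline wander, powerline interference, electrode
noise bursts, ectopic beats, or morphology variability beyond amplitude
jitter; classes are far more separable than clinical data.  Passing tests
on this generator demonstrates that the pipeline is wired correctly and
that the architecture can learn lead-localized and rhythm features — it
does not certify clinical performance.  Anomaly magnitudes are free
parameters of the generator, fixed once at physiologically plausible
values; no published dataset defines them.

## Desk-scale validation conditions

System-level checks train the same architecture at reduced widths
(stem 4, LTCAR 6/8, branch 8, head 32, r 4 — `ecgcoattn.reference`) on a
500-record superclass dataset, batch 16, lr₀ 3e-3, stopping once the
validation macro AUC reaches 0.95 (cap 20 epochs; typically 5–7).  The
reduced run exercises every component of the full protocol; only channel
widths differ from the default configuration.

## Evaluation conventions

Label-based metrics with macro (unweighted) class averaging.  Multi-label
"accuracy" is the mean over labels of per-label binary accuracy
(TP+TN)/N, consistent with label-based evaluation (it is not an
exact-match rate).  AUC is trapezoidal ROC area (ties count one half);
classes observed with a single label value report AUC as missing and are
excluded from the macro mean.  Binarization at 0.5 for multi-label
scores, argmax for exclusive.  Zero-denominator precision/recall/F1 are
reported as 0.

## Numerical and implementation notes

* The network runs on a compact numpy reverse-mode autodiff engine
  (float32); convolution forward/backward are numba-jitted row-vectorized
  kernels, single-threaded and deterministic.  Intermediate gradients are
  freed during the backward sweep (opt-in `retain_grad` for
  class-activation maps) to bound peak memory near 1 GB at batch 16.
* Batch-norm eval statistics use the running estimates; training-mode
  statistics are per-batch with momentum 0.1 and unbiased running
  variance.
* Gradient-weighted class-activation maps follow the standard recipe:
  channel weights are the GAP of the logit's gradient on the chosen
  feature map (default: the multi-scale concatenation, the last body
  feature map), the weighted sum passes ReLU, bilinear resampling to the
  input plane, then min–max normalization (an all-zero map stays zero).
* Degenerate inputs are defined behaviour: constant leads normalize to
  zero; an all-zero trace yields no QRS detections; attention weights are
  strictly inside (0, 1) by construction.
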