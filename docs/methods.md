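# Methods

## Problem and model

The package classifies single 30-s epochs of one EEG channel (3000
samples at 100 Hz) into the five AASM sleep stages W, N1, N2, N3 and REM.
The classifier is deliberately small — 48,226 trainable parameters — so
that it can run in real time on constrained hardware, and it is strictly
one-to-one: each epoch is scored from its own samples, with no temporal
context and no post-hoc smoothing.

The network has three parts:

1. **Feature extraction.** Five blocks, each a 1-D convolution (kernel 3,
   stride 1, padding 1, no bias) → batch normalisation → leaky ReLU
   (slope 0.01) → max pooling (kernel 3, stride 3; omitted in the fifth
   block) → a dual attention stage.  The first block is a standard
   convolution to 64 channels; the remaining four are *group*
   convolutions with 128 channels and 64 groups, which cuts their
   parameters and MACs by the group factor.  Channel-shuffle permutations
   (reshape–transpose–flatten) after blocks 2–4 restore information flow
   between the groups of consecutive grouped convolutions.  The temporal
   length falls 3000 → 1000 → 333 → 111 → 37 (floor arithmetic, no
   padding in the pools) and stays 37 through the fifth block.
2. **Attention (ECSA).** Each block ends with an efficient channel
   attention gate followed by a CBAM-style spatial gate.  The channel
   gate is `sigmoid(conv1d(GAP_time(F)))` with a bias-free kernel whose
   size adapts to the channel count as
   `k = |log2(C)/γ + b/γ|_odd` (γ=2, b=1): floor of the magnitude, then
   bump even values up to the next odd integer, giving k=3 at 64 channels
   and k=5 at 128.  The spatial gate convolves the 2-channel
   (channel-max, channel-mean) summary with one bias-free kernel of
   width 7 and applies one sigmoid coefficient per time point.  The five
   attention stages together cost 93 parameters: 3 + 4·5 = 23 for the
   channel gates and 5·(2·7) = 70 for the spatial gates.
3. **Fusion and head.** After dropout (rate 0.5), three dilated
   convolutions (kernel 3; dilations and paddings 1, 2, 4; channels
   128→32→64→128, each with BN + leaky ReLU) fuse every position with its
   neighbours — the stack's receptive field is 1 + (k−1)·Σd = 15 feature
   points.  Global average pooling over time and a 128→5 linear layer
   (with bias) produce the logits.

### Conventions fixed by the parameter budget

Several micro-decisions are pinned down jointly by requiring the total to
equal 48,226 and the attention cost to equal 93: convolutions carry no
bias (they are always followed by BN), the linear head carries bias,
attention convolutions carry no bias, the spatial kernel is 7 (the CBAM
default), and "parameters" counts trainable scalars only (BN running
statistics are buffers).  The unit tests verify that the floor-then-odd
kernel rounding is the *only* rounding variant consistent with the
93-parameter attention cost.

Complexity is accounted analytically per layer: `k·(C_in/g)·C_out`
weights plus `2C` per BN layer; `k·L_out·C_in·C_out/g` MACs per
convolution, `C_in·C_out` for the linear head; attention gates add
`k_eca·C` and `2·7·L`.  FLOPs, where printed, are `2 × MACs`; pooling,
BN and activations are not counted.  The same accounting is validated
against the instantiated weight arrays for every ablation and width
variant.

### Width multiplier and variants

`width_multiplier_alpha` scales every convolution channel count
(`round(αC)`, minimum 1).  Because a grouped convolution needs its group
count to divide both its input and output channels, each block's
effective group count is `gcd(g, C_in, C_out)`; at α ∈ {0.5, 1, 2, 3}
this leaves the group structure intact while keeping scaled variants
well-formed, and the parameter count is strictly increasing in α.  The
ablation family (group conv only; + shuffle; + attention; attention with
undilated fusion; full model) and the flatten+linear ("FC") head are
plain configuration variants.

Channel shuffle is placed at the output of blocks 2–4 (after the
attention stage); the placement does not affect any parameter count and
is configurable.  The pool kernel (3) is fixed by the length chain
3000→1000→333→111→37 under floor arithmetic.  For the fusion module the
only geometry that preserves length 37 and yields a receptive field of 15
is stride 1 with padding equal to dilation for all three layers, so that
is what the package builds.

## Implementation of the network

The model, its backward passes and the Adam optimiser are implemented
directly on numpy arrays in `microsleepnet.nn` (grouped/dilated
convolution via strided column views and batched matmul, batch norm,
leaky ReLU, max pooling, dropout, the two attention gates, channel
shuffle, GAP, linear).  Every layer's backward pass is verified against
central-difference gradients in float64; training runs in float32.
Weight initialisation is uniform `±1/sqrt(fan_in)` for convolution and
linear weights, BN starts at scale 1 / shift 0, and all randomness flows
through seeded generators.

One numerical choice matters for short trainings: BN running statistics
use a cumulative average over the first batches (effective momentum
`max(0.1, 1/(n+1))`) before switching to the usual 0.1 EMA.  With only
ten batches per epoch, a pure EMA starting from (mean 0, var 1) leaves
inference-mode statistics mis-scaled for several epochs — raw EEG is on
the order of tens of microvolts, so first-layer activation variances are
far from 1 — and the mismatch compounds across the eight stacked BN
layers.  The cumulative start makes inference usable from the first
epoch and is equivalent to the EMA thereafter.

## Training protocol

Adam with fixed learning rate 1e-3, β₁ = 0.9, β₂ = 0.999; L2
regularisation 1e-3 implemented as weight decay on convolution/linear
weights only (BN parameters and biases are not regularised); batch size
200; at most 100 epochs; early stopping when the validation loss has not
improved for 10 consecutive epochs, restoring the weights of the best
validation epoch ("best" = lowest validation loss, the same quantity the
stopper monitors).  The loss is class-weighted cross-entropy on logits,
normalised by the sum of the applied weights; the default weights are
uniform, with `(1, 2, 1, 1, 1)` available to up-weight N1 on severely
imbalanced corpora.

Cross-validation is subject-wise: `subject_kfold` partitions subjects
(k = n gives leave-one-subject-out), and within each fold the training
epochs are shuffled and split 9:1 by stratified sampling into train and
validation sets; the held-out subjects never contribute epochs to either.
Metrics are computed from the 5×5 confusion matrix: accuracy ×100,
one-vs-rest per-class F1 (defined 0, with a warning, for a class absent
from both truth and prediction), macro-F1 as their unweighted mean, and
Cohen's κ = (p_o − p_e)/(1 − p_e) from the observed agreement and the
marginal chance agreement.

## Data handling

EDF/EDF+ recordings are read through mne; hypnograms come either from an
EDF+ annotation channel ("Sleep stage W/1/2/3/4/R/?", expanded to 30-s
epochs) or from a plain-text sidecar with one R&K code per epoch.  R&K
codes map to AASM as W→0, S1→1, S2→2, S3→3, S4→3, REM→4; MOVEMENT and
UNKNOWN epochs are masked out.  Wake is trimmed to at most 60 epochs
(30 min) before the first and after the last non-wake epoch — the trim
never removes sleep.  Signals at other rates are resampled to 100 Hz by
polyphase (anti-aliased) rational resampling; no filtering or amplitude
normalisation is applied anywhere.  Epochs are consecutive,
non-overlapping, half-open 3000-sample windows aligned 0-based with the
labels; a trailing partial window is dropped with a warning, and a
signal/label disagreement beyond one epoch is an error.

The package also contains a minimal EDF/EDF+ *writer* (16-bit records,
symmetric physical/digital ranges so the quantisation error is bounded by
`phys_max/32767`, optional timestamped-annotation channel) used to
produce self-contained fixtures; reading those fixtures back goes through
the same mne path as real data.

## Synthetic data: what it emulates and what it does not

The generator produces labelled epochs carrying the hallmark features a
scorer uses, over a 1/f (default exponent 1) Gaussian background:

| stage | content | default |
|---|---|---|
| W | alpha bursts 8–13 Hz, 25 µV, 1–3 s | union covers 55–70 % (> 50 % required) |
| N1 | theta runs 4–7 Hz, 20 µV + 1–3 vertex sharp transients (60 µV, 0.2 s) | theta covers 35–50 % |
| N2 | 2–5 spindles (11–16 Hz, 25 µV, 0.5–1.5 s, Hann-tapered) + 1–3 K-complexes (biphasic, 100 µV, 0.7 s) | |
| N3 | slow-wave runs 0.5–2 Hz, 80 µV | union covers 25–40 % (≥ 20 % required) |
| REM | low-amplitude background + 2–4 asymmetric sawtooth runs (2–4.5 Hz, 35 µV, 1–3 s) | |

Event intervals are annotated (non-overlapping per kind) and serve as
ground truth for CAM localisation.  Whole nights are first-order Markov
chains over stages starting in W, with a plausible default transition
matrix.  Band edges, amplitudes, coverages and rates are all exposed in
`SyntheticConfig`; the defaults were chosen once so that the five classes
are cleanly separable (a depth-6 decision tree on Welch band powers
exceeds 95 % accuracy — the property the end-to-end training check rests
on) while keeping amplitudes in a realistic EEG range.

The generator makes no claim of physiological realism: phases are
random, events are deterministic templates with drawn amplitude/position,
there are no artifacts, no inter-subject variability, no scorer noise,
and class boundaries are far sharper than in real PSG.  Passing the
end-to-end checks therefore demonstrates that the pipeline — generator,
data handling, network, optimisation, metrics, CAM — is correct and that
the architecture can learn stage-defining waveforms; it says nothing
about accuracy on real recordings, which requires the full public
corpora and hours of training.

## Class activation mapping

With a GAP+linear head the class score decomposes over time, so the
evidence curve `cam_raw[x] = Σ_k w_k^C f_k(x)` is read off the
post-fusion feature map (128×37) and the head weights of the target
class, excluding the bias.  The curve is min–max normalised to [0, 1]
(a constant curve maps to zeros rather than NaN) and linearly
interpolated to the 3000-sample epoch.  `localization_score` is the mean
CAM inside annotated feature-wave intervals minus the mean outside;
positive values mean the attention concentrates on the annotated events.
The package computes CAM only for the GAP head, where the decomposition
is exact.

## Problem sizes used in the checks

The end-to-end check trains the full model on 2,000 balanced synthetic
epochs with 500 for validation and 500 held out, batch size 200, for up
to 6 epochs at a fixed seed — on this corpus the validation accuracy
saturates within the first few epochs, so the short budget is sufficient
while keeping the run cheap on one CPU.  The CAM localisation check uses
150 fresh N2 epochs (≥ 100 correctly classified) and a one-sided sign
test at p < 0.05.  Metric implementations are compared with brute-force
re-implementations on 1,000 random confusion matrices at 1e-12, and with
sklearn's implementations as an independent oracle.

## Known limitations

* No GPU path; the numpy implementation is tuned for small batches on a
  CPU and would not scale to the full public corpora in reasonable time.
* FLOP figures depend on the counting convention; this package documents
  and uses 2 × MACs with the per-layer formulas above.
* CAM is a linear read-out of the final feature map; it localises
  evidence at the 37-point feature resolution (≈ 0.8 s), not at sample
  resolution.
* The EDF writer supports exactly what the fixtures need (one sampling
  rate, whole-second signals); it is not a general-purpose exporter.
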