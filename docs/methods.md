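# Methods

## The decoder

`mseegnet` decodes epoched motor-imagery EEG trials `x ∈ R^{C×T}` (C
electrodes, T samples at 250 Hz) into class probabilities with a
three-branch multiscale EEGNet:

1. **Temporal stage.** Branch *i* applies F1_i temporal filters of length
   K_i samples (2D kernels of size (1, K_i), "same" zero padding, no bias),
   followed by batch normalization. The stock branches double both
   quantities from one branch to the next — F1 = {4, 8, 16},
   K = {16, 32, 64} — so the three branches see ~64 ms, ~128 ms and ~256 ms
   of signal per filter tap at 250 Hz.
2. **Fusion transmission 1.** The branch-1 temporal output (4 maps) is
   concatenated along the map axis onto branch 2's temporal output
   (8 maps); branch 2's depthwise stage therefore reads 12 maps.
   Concatenation is the only fusion operation consistent with the unequal
   map counts; values pass through unchanged.
3. **Depthwise spatial stage.** Per input map, D = 2 filters of size
   (C, 1) collapse the electrode axis (learned spatial montages), then
   BN → ELU → average pooling (width 4) → dropout. A per-filter max-norm
   constraint of 1.0 regularizes the spatial filters.
4. **Fusion transmission 2.** Branch 2's depthwise output (24 maps) is
   concatenated onto branch 3's (32 maps); branch 3's separable stage reads
   56 maps.
5. **Separable stage.** Depthwise temporal convolution (kernel (1, 16),
   same padding) then a pointwise 1×1 convolution to F2_i = F1_i·D output
   maps, BN → ELU → average pooling (width 8) → dropout.
6. **Efficient channel attention (ECA).** Per branch, each output feature
   map m is gated: z_m = GAP(X_m) (global average over the remaining
   spatial/time axes), a length-k 1D convolution slides over the *map* axis
   of z (zero "same" padding, scalar bias), a sigmoid yields gates in
   (0, 1), and X̃ = X ⊙ gate. The kernel width follows the adaptive rule
   k = nearest-odd((log2(M) + b)/γ) with γ = 2, b = 1 (ties round up,
   floor at 1), which gives k = 3 at M = 32; k = 3 is also the default
   override for all branches. ECA adds only k + 1 parameters per branch.
   The "channels" attended over are feature maps, not electrodes — after
   the depthwise stage each map is a learned linear combination of
   electrodes. ECA weights are not shared across branches.
7. **Head.** The three gated stacks are flattened, concatenated, passed
   through dense(32) → ELU → dense(n_classes) → softmax. The dense layers
   carry a max-norm constraint of 0.25.

Ablation switches reduce the model cleanly: `use_fusion=False` and
`use_eca=False` give three independent EEGNets; a single-branch config is
the canonical EEGNet layer stack (temporal → depthwise → separable →
dense).

### Choices the architecture description leaves open

* **Pooling widths and dropout** are not specified by the architecture's
  description; the canonical EEGNet values (4 and 8, dropout default 0.25,
  exposed per branch) are adopted. Without pooling the flattened head
  would be enormous.
* **Fusion taps post-BN / post-pooling outputs** — the stage outputs as
  defined, so fused operands share scale statistics.
* **Head activation.** Two stacked linear layers would collapse to one
  linear map; ELU (the network's activation elsewhere) follows dense(32).
* **Rounding in the ECA kernel rule** is nearest-odd with ties rounded up;
  the rule's only stated anchor (M = 32 → k = 3) is reproduced by any
  reasonable rounding, and nearest-odd also floors correctly at M = 1.
* **Initialization** is seeded Glorot-uniform; max-norm constraints
  (1.0 depthwise, 0.25 dense) follow the EEGNet lineage and can be
  disabled via `ModelConfig(max_norm=False)`.

## Implementation: NumPy training stack

The network, backpropagation, and Adam are implemented directly on NumPy.
Convolutions are lowered to im2col windows and BLAS matrix products; the
temporal stage runs in a maps-major "rows" layout `(maps, batch·C·T)` so
batch-norm reductions, fusion concatenation, and the depthwise batched
matmul all touch contiguous memory. Two further optimizations matter on a
single CPU: the im2col matrices of the training set are precomputed once
per run (they depend only on the data, ~10 bytes per sample per kernel
tap, capped at 2.5 GB before falling back to per-batch construction), and
the gradient with respect to the raw input batch is skipped during
training (the temporal convolutions are the first layer). All arithmetic
is float32; BN statistics accumulate in float64. Analytic gradients of
every layer are verified against central finite differences in the test
suite.

## Training and evaluation

Adam (lr 0.001, β = 0.9/0.999), batch size 64, cross-entropy, a fixed
epoch budget (default 1000) with seeded reshuffling each epoch, no
validation split or early stopping; the final model is evaluated. Loss
histories have exactly one entry per epoch; a non-finite loss aborts with
a diagnostic. Determinism: weight init derives from the model seed, batch
order from the train seed, dropout noise from the model seed — identical
seeds reproduce identical loss histories bit-for-bit.

Metrics: accuracy = 100·trace/total of the confusion matrix (the
multiclass reading of the binary TP/TN formula, forced by the 4-class
tasks); Cohen's kappa = (P_o − P_e)/(1 − P_e) with P_e from the row/column
marginals. The Wilcoxon signed-rank test uses the exact null distribution,
computed by generating-function convolution over the signed-rank sums —
mathematically identical to enumerating all 2^n sign assignments, feasible
far beyond the n = 9–14 subject counts it is used for. Zero differences
are dropped (Wilcoxon's prescription), ties get average ranks, two-sided
by default; both policies are arguments. scipy's normal-approximation mode
serves as an independent cross-check in the tests (scipy's exact mode
refuses ties, which is why the enumerator is in-package).

Protocols: **within-subject** trains one model per subject on designated
sessions and evaluates on held-out sessions; **LOSO** holds out one whole
subject per fold. Reports carry per-subject accuracy/kappa/confusion plus
mean/SD aggregates. The **ablation grid** runs the four structure
combinations (fusion × ECA, parallel branches always on) and attaches
exact Wilcoxon p-values of each reduced row against the full model.

## The synthetic generator

The generator (module `synthetic`) emulates the single physiological fact
the decoder exploits: class-dependent event-related desynchronization of
band-limited rhythms over lateralized electrode groups. Per electrode,

    x_c(t) = g_s · [pink_c(t) + a_α·m_α(y,c)·s_α(t) + a_β·m_β(y,c)·s_β(t)]

with independent unit-variance 1/f^1 background noise per electrode
(spectral synthesis), common-mode narrowband alpha (8–12 Hz, amplitude
1.0) and beta (13–30 Hz, amplitude 0.8) rhythms, per-subject log-normal
gains (σ = 0.1), and modulation gains m = 1 − depth on the class's
suppressed group: left hand → right-lateral alpha, right hand →
left-lateral alpha, feet → midline beta, tongue → both lateral groups at
0.3·depth. Groups are index-based (first/last C/3 electrodes lateral,
middle midline). The oscillation amplitudes were fixed once, before the
decoder experiments, from a band-power pilot: they put the in-band
rhythm-to-background ratio near 12:1, so depth 0.9 is an easy, clearly
separable regime and depth 0 is exactly null.

What it does **not** emulate: volume conduction/electrode geometry, eye or
muscle artifacts, within-session non-stationarity, realistic amplitude
units. Passing tests therefore show that the architecture, optimizer,
protocols and attribution behave correctly on data with the ERD structure
— not that published-benchmark accuracies on real recordings are reproduced.

## Segmentation

Epochs are exact integer slices of the continuous recording — no
filtering, no artifact handling. Windows are seconds relative to cue
onset, half-open [start, end), 0-based, so [1.5 s, 6 s] at 250 Hz yields
exactly 1,125 samples and [0 s, 4 s] yields 1,000. Resampling (for 500 Hz
sources) is anti-aliased polyphase (`scipy.signal.resample_poly`), applied
before segmentation so window arithmetic stays at 250 Hz. Real-dataset
loading (GDF via mne) is optional; missing files raise a distinct
`ExternalDataMissing` error and never fail the test suite.

## Grad-CAM attribution

Attribution targets the temporal-stage outputs — the only activations that
retain the electrode axis. The gradient of the target-class logit is taken
w.r.t. those activations, averaged globally per feature map into map
weights, and the weighted activation sum is rectified; temporal stages are
unpooled so maps come out at full (C, T) resolution (nearest-neighbour
upsampling covers custom pooled variants). Because the method is
activation-weighted, it highlights where the rhythm IS: on synthetic ERD
data the class's suppressed lateral group carries the *lowest* attribution
and the intact groups the highest — the validated oracle asserts exactly
that contrast (suppressed < midline and < intact lateral group in ≥ 80% of
correctly classified trials). Per-electrode means are exported for
topography-style rendering in external tools; scalp-map drawing itself is
out of scope (no electrode coordinates are assumed).

## Problem sizes used by the test suite

The suite runs on one CPU. Unit and property tests use C = 9, T = 250,
tens of trials, and ≤ 40 epochs. The synthetic-recovery acceptance
experiment uses the full architecture (C = 22, T = 500, 4 classes,
modulation depth 0.9): 50 trials/class/session × 2 sessions, training on
session 0 (200 trials) for 100 epochs at batch 64, three seeds for the
full model and one for the no-fusion/no-ECA ablation; all runs reach 100%
held-out accuracy against the 80% criterion. The monotonicity property
(accuracy non-decreasing in modulation depth over {0, 0.3, 0.6, 0.9}) runs
at C = 9 with three seeds, allowing one ≤ 2-point inversion.

## Known limitations

* CPU NumPy training is ~minutes per model at desk scale; the 1000-epoch
  default budget on real-size data (C = 22, T = 1125, hundreds of trials)
  is hours — realistic use of this package at full benchmark scale would swap the
  `nn` backend for a GPU framework behind the same module surface.
* The exact Wilcoxon null assumes exchangeable signs; with heavy zero
  inflation the drop policy shrinks n (the `keep` policy is provided).
* BN statistics in LOSO are global (no per-subject adaptation), matching
  the protocol's strict unseen-subject premise.
* The generator's common-mode alpha puts rhythm on midline electrodes, so
  midline attribution is non-zero by construction; lateralization contrasts
  are the meaningful attribution signal.
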