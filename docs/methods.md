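# Methods

This note documents the model, the choices made where the design was
genuinely open, the synthetic data the package is validated on, and the
numerical conventions — at the level of detail a maintainer needs to
modify the code safely.

## Problem formulation

A fixed-length single-lead ECG segment (default 30 s at 128 Hz,
`L0 = 3840` samples) is treated as a 1D object-detection scene.  Each
heartbeat is an object `(c, b)` with class `c ∈ {NonAF, AF}` and interval
box `b = (x, w)` in coordinates normalized by the segment length; the box
center is the annotated R peak and the default width is 400 ms (13.3 ms⁻¹
of the 30 s axis).  Alternative widths (300/500 ms fixed, or adaptive:
half the local R-R interval, estimated as the mean of the adjacent
intervals) are available through `BoxWidthStrategy`.  AF and atrial
flutter annotations form the positive class; beats whose R peak falls in
an unannotated gap are NonAF.

The model emits a fixed set of `N` predictions (default 100, far above
the ~50 beats a 30 s segment can hold at 200 bpm); slots not matched to a
beat must predict the third class, Non-obj.

## Preprocessing chain

Fixed order: resample to 128 Hz (polyphase, annotation indices rescaled
and rounded) → order-5 Butterworth band-pass 0.5–40 Hz, applied forward
and backward so beat indices stay aligned → non-overlapping segmentation
(trailing remainder dropped; half-open windows, 0-based indices) →
signal-quality gate → z-score normalization (constant segments map to
zero and are flagged) → optional polarity-inversion augmentation (the
training set is doubled with `x → −x`; labels unchanged).

**bSQI.**  The quality index is named in the source literature but not
defined; this package uses the standard beat-agreement construction: two
structurally different classical QRS detectors (a Pan–Tompkins-style
derivative-energy detector on the 5–15 Hz band, and an amplitude-threshold
detector on the 8–25 Hz band) are run on the filtered, unnormalized
segment, their detections are greedily matched one-to-one within 150 ms,
and `bSQI = #matched / #union`.  Segments with bSQI < 0.8 are discarded;
zero detections on both detectors define bSQI = 0.  On clean synthetic
segments both detectors find the same R peaks (bSQI = 1); broadband noise
at −5 dB SNR reliably pushes bSQI below the gate.

## Architecture

* **Backbone** — stem convolution (kernel 3, batch norm, ReLU), a
  stride-3/kernel-3 max pool, four residual blocks (two kernel-3 convs +
  BN each, channel count doubling in the first conv, 1×1 projection on the
  skip when widths differ), each followed by a stride-2 pool, then a 1×1
  convolution to `D`.  Default channel plan 16→32→64→128→256, total
  stride 48.  Both plans are configurable; inputs are right-padded with
  zeros to a stride multiple.
* **Encoder** — post-norm transformer layers; queries and keys receive the
  token-position embedding (integer index, temperature 10 000), values do
  not.  FFN hidden width is 4·D.
* **Decoder** — content queries are learned embeddings; positional queries
  are `MLP(cat(PE(x), PE(w)))` with temperature 20, the two-layer MLP
  shared across layers.  Self-attention uses Q=K=content+positional,
  V=content; cross-attention uses Q=LN(content+self-out)+positional,
  K=memory+PE, V=memory.  Each layer's unshared 3-layer box head predicts
  sigmoid-space offsets applied as `σ(Δ + σ⁻¹(b_prev))` (clamped at
  ε=1e-4), and its unshared 2-layer class head emits 3-class logits.
  Boxes are detached between layers, so each layer's heads receive
  gradients only from that layer's auxiliary loss (asserted by test).
  Initial anchors are evenly spaced centers `(q+0.5)/N` at the fixed
  initial width (a random-uniform option exists behind a flag).

### Positional-encoding resolution (a deliberate deviation)

Two choices here departed from the obvious reading, both verified to be
load-bearing at desk scale:

1. **Coordinate scale.**  Encoding the normalized coordinate as `2πx`
   with T=20 puts at most one sinusoid cycle across the segment, so the
   query–key positional kernel `PE(x_q)·PE(x_k)` is almost flat and
   cross-attention starts (and stays) uniform; training then never leaves
   the constant-output saddle.  The package scales coordinates by
   `2π·32` (`ModelConfig.pe_scale`) so the embedding contains frequencies
   that resolve individual feature tokens.
2. **Shared embedding space + positional prior at init.**  Cross-attention
   keys embed the *normalized token center* with the decoder's encoding
   function (the same function that builds positional queries), the
   positional MLP is initialized as a ReLU-shifted pass-through of
   `PE(x)`, the decoder attention Q/K projections start as the identity,
   and positional embeddings enter attention with a gain of 2
   (`ModelConfig.pe_gain`).  Together these make the decoder's attention
   begin as a soft window centered on each query's anchor.  Everything
   remains fully learnable; at large training scale this is only an
   initialization, but at desk scale it is the difference between
   convergence in ~300 steps and no convergence at all.

## Matching and losses

The matching cost uses the raw class probability (not its log):
`−φ_cls p̂(c_i) − φ_giou GIoU + φ_L1 L1` with φ = 2:5:2.  The assignment
is solved exactly; the public `hungarian_match` breaks ties toward the
lexicographically smallest optimal assignment (sequential row fixing over
the exact solver) so results are reproducible, while the training loop
uses the plain solver (float costs tie with probability zero).

Per decoder layer: the classification term is *averaged over all N
slots* (`α = 0.1` for Non-obj targets) and the box term
`λ_giou (1−GIoU) + λ_L1 L1` is *averaged over the M matched beats*;
λ = 1:5:2.  The total is the sum over layers (auxiliary deep
supervision); disabling it (`aux_loss=False`) supervises only the final
layer.  Loss variants: focal (`−α(1−p)^γ log p` applied uniformly to all
targets, so γ=0, α=1 recovers plain cross-entropy) and class-weighted
cross-entropy (inverse-frequency weights over {NonAF, AF}, normalized to
mean 1, Non-obj keeping its 0.1).

## Contrastive denoising

Per batch, `n_groups` (default 5) groups of noise queries are built from
the ground truth: for each beat a positive query (center shift uniform in
`(−λ1 w/2, λ1 w/2)`, λ1 = 0.5) and a negative query (shift magnitude
uniform in `[λ1 w/2, λ2 w/2]`, λ2 = 1.0, random sign — still inside the
original box).  Labels are flipped independently with probability
γ = 0.2; the flipped label's embedding is the content query and the
noised box's embedding the positional query.  Widths are never noised.
The self-attention mask blocks ordinary↔noise attention in both
directions and all cross-group noise attention; padding slots (groups are
padded to the batch maximum M) are fully masked except self-attention.
Positives are supervised toward their true label and box, negatives
toward Non-obj only (no box term, consistent with the matched loss's
`c ≠ ∅` indicator); the classification term averages over all valid noise
queries and the box term over positives, summed across decoder layers.
With `contrastive=False` only positive-style queries at scale λ1 are
generated (the plain-denoising ablation); at inference no noise queries
exist.  λ1, λ2, γ and the group count are not given numerically in the
source; the defaults follow detection-transformer convention and are all
configurable.

## Optimization

Adam (β = 0.9/0.999, no weight decay) with the per-epoch schedule
`η = η_base/(1 + 10·T_cur/T_max)²` (the printed formula is typographically
ambiguous; this is the standard annealing reading, and it is monotone
decreasing).  Full-scale defaults: η_base = 1e-4, batch 64, T_max = 30.
A single seed drives weight initialization, shuffling and denoising
noise; two runs with the same seed produce identical loss curves, and
the best checkpoint by validation matched loss is restored after
training.  Divergence (non-finite loss or matching costs) aborts with a
diagnostic.

The tensor engine computes in float32 (the CPU-practical choice; float64
is available and used by the finite-difference gradient tests).

## Evaluation protocol

Predictions with the Non-obj argmax are dropped; survivors keep their max
class probability as score and same-label boxes with IoU > 0.8 are merged
transitively, keeping the highest-scoring member.  Localization uses
greedy score-descending one-to-one matching (PASCAL convention —
deterministic; the source does not name its matcher) with TP at
IoU > 0.5; MAE is the mean absolute center error over TPs, in ms and in
samples.  Beat-level classification counts a beat correct only when
localized and correctly labeled; unlocalized beats count against their
class's sensitivity, and localization false positives count against the
predicted class's precision.  Macro metrics average the two real classes;
a class absent from the ground truth is reported as absent and the macro
degenerates to the present class.  Accuracy is only reported at segment
level, where a true-negative count exists.

Segment labels: majority rule (AF iff AF share > θ, default 0.5, strict)
or time-consecutive rule — AF iff a run of consecutive AF-labeled beats
covers at least `min_af_span_s` (default: the segment duration), the
covered interval extending one median R-R beyond the run's first and last
beat, clipped to the window.  The extension is needed because beat
*centers* of a run that fills the whole window still span less than the
window; with it, a full-segment AF run always qualifies, and on
quasi-periodic fixtures the two rules agree except in knife-edge cases a
few milliseconds from the threshold.

Calibration uses the matched beats' AF probability (renormalized over the
two real classes): ECE over 10 equal-width bins and the Brier score.
False-positive AF detections can be attributed to confounding rhythm
categories through a configurable annotation-symbol map.

## Synthetic data

The generator emulates only the statistical signatures the detector
exploits — it is not a biophysical ECG model:

* R-R intervals are log-normal with configurable mean heart rate and
  coefficient of variation (sinus ≈ 0.03, AF ≈ 0.2; AF and sinus fixture
  sets are separable by R-R CV alone with a large effect size);
* each beat is a Q-R-S triplet of Gaussians (R amplitude 1, ~80 ms
  complex) plus a T wave; sinus beats add a P bump 160 ms before the R
  peak; AF segments add band-limited 4–9 Hz noise (the F-wave surrogate)
  and no P wave;
* additive white noise and a 0.1–0.3 Hz sinusoidal baseline wander.

Mixture datasets randomize heart rate (55–100 bpm), noise level
(0.01–0.06 relative to the R amplitude) and F-wave amplitude per segment;
the manifest records every per-segment spec, so stores regenerate
bit-identically.  What passing tests on this data do **not** show:
robustness to ectopy (PAC/PVC/bigeminy), conduction block, electrode
artifacts, morphology variation across patients, or any real-data
distribution shift — real AF/sinus morphology is far richer than these
templates.

## Desk-scale profile and problem sizes

The package's end-to-end checks train a reduced configuration chosen to
fit a single CPU: 10 s segments, D=32, 2 heads, 2+2 transformer layers,
N=40 queries, backbone channels (8,16,32,32,32) with pooling (3,2,2,1,1)
(total stride 12), 3 denoising groups, batch 16, 12 annealed epochs from
η_base = 1e-3 on 800 synthetic segments (the larger base rate compensates
for a run several orders of magnitude shorter than a full-scale one).
This run reaches localization F1 ≈ 0.98, center MAE ≈ 1.4 samples, beat
macro-F1 ≈ 0.98 and segment accuracy 1.0 on 200 held-out segments in
about two minutes.  Ablation checks (3 seeds, 600 segments) confirm the
expected directions: removing the auxiliary loss or denoising does not
improve held-out localization.

## Known limitations

* The numpy autodiff engine is single-threaded and eager; full-scale
  training (D=128, 30 s segments, tens of thousands of segments) is out
  of its practical reach — the architecture supports the configuration,
  but expect hours per epoch.
* Hungarian matching is exact but per-segment; very large N would make
  the lexicographic tie-break quadratic in practice.
* The WFDB adapter is untested against the live PhysioNet databases in
  this repository (the dependency is optional); its rhythm-interval
  construction assumes aux-note rhythm changes of the `(X` form.
* Batch-norm statistics come from desk-scale batches; evaluation uses
  running averages, so very small training runs can show a small
  train/eval gap.
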