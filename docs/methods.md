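# Methods

## Scope and intent

`crtnn` re-implements a dual-stream attention convolutional-recurrent
architecture for EEG emotion recognition, together with the preprocessing
pipeline of the two standard affective-EEG layouts (a 32-channel layout
with 1–9 self-assessment ratings and a 3 s pre-stimulus baseline, and a
62-channel layout with categorical negative/neutral/positive labels) and a
synthetic-EEG generator.  The two reference corpora are access-restricted
and training on them is GPU-scale, so the package's claims are the ones
checkable on a desk: exact shape traces, exact trainable-parameter budgets,
attention normalisation, causal receptive fields, label-scheme arithmetic,
and learning behaviour on synthetic data with known ground truth.  Headline
accuracies on the real corpora are explicitly out of scope.

## Numerical core

No deep-learning framework is used.  The models run on a small tape-based
reverse-mode autodiff engine (`crtnn.autodiff`) written on numpy:
elementwise ops, batched matmul, reductions, shape ops, a multi-channel 1-D
convolution and max pooling, each with an analytic backward pass verified
against central finite differences in the test suite.  The convolution has
two algebraically identical paths: narrow or dilated kernels use one GEMM
per kernel tap; wide dilation-1 kernels (the two 40-wide stream
convolutions) use the cross-correlation theorem with transform length equal
to the input length, which is exact for the valid output range because the
linear correlation never wraps.  The tests assert that both paths agree and
that both differentiate correctly.

All parameters are float32, initialised ``U(-1/sqrt(fan_in),
1/sqrt(fan_in))`` from a seeded `numpy.random.Generator`; building a model
twice with the same config yields bit-identical weights, and single-device
training is deterministic under the training seed.

## Model

The classifier consumes 3 s samples shaped ``(B, 3, C, 128)`` — three
chronological 1 s windows of ``C`` channels at 128 Hz.

**Channel-selection attention (CSAM).**  Per window, channels are scored
from their time-averaged activity: linear ``C -> 2C``, then a kernel-3
1-D convolution over the three window positions applied twice *with one
tied weight set*, tanh after each application, linear ``2C -> C``, sigmoid,
softmax over channels.  The tied convolution is a deliberate reading: the
published per-block budget (16.5 K at C = 32) is only reproduced when the
two listed convolution rows share one weight set (2112 + 12 352 + 2080 =
16 544).  Both a sigmoid-then-softmax gate (default) and a softmax-only
gate are available (`csam_gate`), since the block's table lists a sigmoid
while its prose describes a channel softmax; applying both honours the two
sources.  Weights are computed per window rather than shared across the
three windows (the source is silent; per-window is the more general
reading).  Squeeze-excitation (reduction ratio 4) and efficient-channel
attention (adaptive odd kernel, 3 at C = 32) are provided as drop-in
comparisons under the same shape contract.

**Fixed stream (MHSA-CRNN).**  Windows are folded into the batch axis;
each ``(C, 128)`` window is convolved with 40 full-height ``(32, 40)``
filters at stride 1 (valid, width 89), ELU-activated, max-pooled ``(1,
75)`` stride 10 (width 2), flattened to 80; the three windows form a
length-3 sequence for a two-layer LSTM (hidden 64); 8-head self-attention
(dim 64, per-head 8) follows.

**Adaptive stream (SA-CRNN).**  The three windows are concatenated in time
to a ``(C, 384)`` map.  Stride and pooling derive from the kernel width
``w``: conv stride ``floor(w/10)``, pool kernel ``(1, floor((w-1)/2))``,
pool stride ``floor(w/10)`` — floor division throughout, which for ``w =
40`` gives widths 87 and 18 and a flattened feature of 720, the stream's
stated recurrent input size.  The formulas are taken literally, so widths
3–9 yield stride 0; such configurations are representable by
`adaptive_params` but rejected when building the stream.  The single
720-vector is repeated into a length-3 sequence so this stream's output
aligns with the fixed stream's ``(B, 3, 64)`` for concatenation; repetition
is the one interpretation implemented (the alternative — unrolling hidden
state — is noted as an open design point in the source's terms).

**Recurrent bias convention.**  LSTMs carry one bias vector per gate set
per layer, ``4*(d_in*d_h + d_h^2 + d_h)`` parameters per layer.  This is
the only convention under which the adaptive stream's published budget
(285.2 K) is exact: 51 240 (conv) + 200 960 (layer 1) + 33 024 (layer 2) =
285 224.  Frameworks whose LSTM primitive carries two bias vectors count
64×4 more per layer.

**Global extractor (MHSA-TCN).**  The stream outputs are concatenated along
the window axis to ``(B, 6, 64)`` and read as a 6-channel sequence of
length 64: the recurrent feature axis serves as the temporal axis — the
only reading that yields the published ``(B, 25, 64)`` output with
25-channel hidden layers.  Four residual blocks (kernel 2, dilations 1, 2,
4, 8) apply two weight-normalised causal convolutions each, ELU and dropout
after each convolution, plus a residual connection (1×1 projection on
channel change, no post-addition activation).  Self-attention (8 heads,
embedding 64) sits between the first and second hidden layers and attends
across the 25 channel positions; 64 is divisible by 8 heads, 25 is not.
The block activation is ELU for consistency with the streams, and the
dropout default is 0.1; neither is pinned by the source, both are
config-exposed.

**Classifier.**  Mean over the 25 channel positions gives a 64-vector;
an affine map to ``n_classes`` (130 parameters for two classes, 195 for
three) and a softmax produce the class probabilities.  Pooling over
channels is the only reading under which the published 130-parameter
classifier is well-formed (classifying the last time step would need 52).

**Receptive-field bookkeeping.**  The stack's receptive field is reported
as ``F = (k-1) * sum(d_i) + k``.  Taken literally this describes a causal
ladder with one convolution per listed dilation *plus a leading dilation-1
convolution* (``F = 1 + (k-1)(1 + sum d_i)``); `build_measurement_stack`
constructs exactly that ladder, and the perturbation-based measurement in
the tests confirms the formula on it (17 for k = 2, d = 1, 2, 4, 8).
Counting both convolutions of every residual block is exposed as
``convs_per_level=2``.

**Unreconciled published budgets.**  Under the stated dimensions the fixed
stream counts 138 024 parameters and the global extractor 26 265; the
published table lists 285.7 K and 138 K for these rows, which no
configuration consistent with the stated dimensions reproduces.  They are
recorded here and are not targets; the three reproducible budgets (16 544,
285 224, 130) are asserted exactly.  The published "total model params
2.90 M" is read as approximate float32 storage (726 K × 4 bytes), not as a
second parameter count.

## Preprocessing

Polyphase anti-aliased decimation (`scipy.signal.resample_poly`) brings
trials to 128 Hz; upsampling is refused.  Trials are cut into
non-overlapping 1 s windows (overlap is never used).  For the
baseline-bearing layout the arithmetic mean of the first three 1 s segments
is subtracted elementwise from each of the remaining 60, which are then
grouped chronologically into non-overlapping triples: 20 samples per 63 s
trial, 800 per 40-trial subject.  Segment counts not divisible by three are
truncated (relevant for long clips without a fixed stimulus length);
grouping never crosses trial boundaries.

Ratings map to classes with the annotation schemes: binary — low ``[1, 5]``
/ high ``(5, 9]``; ternary — low ``[1, 4]`` / medium ``(4, 6]`` / high
``(6, 9]``.  Boundary scores belong to the lower class (intervals closed
above).  Splits are per subject (subject-dependent protocol): a stratified
8:2 holdout and stratified 10-fold cross-validation are both available;
cross-validation is the default evaluation and the holdout a flag.  No
re-referencing, band filtering or artifact rejection is applied.

## Synthetic data

Each trial is Gaussian broadband noise (SD 1.0) plus, during the stimulus
window only, a class-dependent sum of band-limited sinusoids: three random
frequencies per band, random phases, independent per channel, amplitude 2.0
scaled by ``1/sqrt(n_components)``.  Default class signatures are theta
(4–7 Hz), alpha (8–13 Hz) and low-gamma (30–45 Hz) for classes 0, 1, 2.
Band-power differences are the minimal structure a spectro-temporal
classifier can exploit, which keeps the generator honest about what passing
tests show: that the pipeline and architecture can extract spectral class
structure — not that they would reach any particular accuracy on real EEG,
which has artifacts, nonstationarity, volume conduction and inter-subject
variability the generator deliberately omits (no forward head model, no
blinks).

Ratings are drawn backwards from the latent class: the class selects its
annotation interval and the rating is drawn uniformly inside it (an epsilon
off the shared boundary), so downstream annotation recovers the latent
class exactly — this round-trip is asserted.  With an
`informative_channels` subset, only those channels carry the class signal;
the tests verify by permutation that the remaining channels are
class-silent.  The 62-channel layout assigns balanced categorical labels
(5 clips per class at the default 15).

Desk-scale defaults are 2 subjects × 24 trials (480 samples per subject
after preprocessing); the full 32 subjects × 40 trials is a config choice
away.

## Training and evaluation

Adam (learning rate 0.001, batch size 128) on cross-entropy; 30 epochs is
the working default (40 for the 62-channel 3-class layout), with no
schedule, weight decay or early stopping unless the caller passes a target
training accuracy to stop at.  Cross-validation trains a fresh model per
fold (fold index added to the init seed) and reports per-fold accuracy and
confusion matrices plus mean ± SD across folds.  The test suite exercises
learning at reduced sizes chosen as desk-scale working points: the
separable default study is fit with early stopping at 96 % training
accuracy, cross-validation folds train for 8 epochs, and the
attention-relevance and ablation-direction checks use 16-trial subjects
with 8 and 12 epochs over 5 seeds — on the strongly separable synthetic
task the models converge to ceiling within those budgets, so longer
schedules would not change the assertions.

## Known limitations

* The synthetic task is far easier than real affective EEG; accuracy
  numbers obtained on it say nothing quantitative about the real corpora.
* The engine is CPU-only and single-device; no mixed precision, no ONNX.
* Bidirectional or deeper recurrent variants, gated/separable temporal
  convolutions and learned positional encodings are out of scope.
* The 8:2 holdout and 10-fold cross-validation are provided side by side;
  no claim is made about how the original experiments nested them.
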