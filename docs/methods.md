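# Methods

## Problem and model

A nanopore event is a 1-D blockade-current series whose length depends on
how long the molecule occupied the pore; lengths differ by orders of
magnitude between events, so a fixed-input network cannot consume them
directly. The package's sequence-to-image (S2I) module maps any series to a
fixed `l × l` image, and a Transformer encoder–decoder classifies the
image.

### S2I transform

Order of operations is PAA first, scaling second: the piecewise aggregate
approximation averages the raw series over `l` equal-width windows
(fractional sample overlap weighted exactly, so non-divisible lengths and
even `l > n` — sample repetition — are handled by one rule), and min–max
scaling then fixes the value range. Scaling before PAA would change the
window means; the chosen order keeps PAA a pure time-axis operation.

Scaling defaults to `[0, 1]`; the `[-1, 1]` variant is selectable. The
polar angle is `arccos` of the scaled value **directly** — with unit
scaling the angles live in `[0, π/2]`, with symmetric scaling in `[0, π]`.
Radii `(i+1)/l` are computed and stored for fidelity to the polar-encoding
picture but do not enter the Gramian matrices: angles alone determine
GASF/GADF. `arccos` inputs are clipped with tolerance `1e-12` to guard
against float drift at the endpoints; genuine violations raise.

GASF is `cos(φ_i + φ_j)`, equivalently the outer-product form
`x̃x̃ᵀ − √(1−x̃²)√(1−x̃²)ᵀ` with **elementwise** squares (the matrix forms
are verified equivalent to the trig forms to `1e-10` in the tests). The
GASF diagonal equals `2x̃_i² − 1`; inversion returns
`√((diag+1)/2) = |x̃_i|`, which equals `x̃_i` only for unit scaling —
symmetric-range inversion is refused as sign-ambiguous rather than
silently wrong.

MTF ranks samples into `n_bins` equal-count quantile bins (stable sort, so
ties break by sample order), estimates the first-order transition matrix
`W`, and sets `M_ij = W[bin(i), bin(j)]`. Bins with no outgoing transition
keep an all-zero row — no probability mass is invented. Default
`n_bins = 8`. RP is the scalar absolute-difference recurrence
`|s_i − s_j| ≤ ε` without time-delay embedding (no embedding parameters are
part of this design); default `ε = 0.1` on the unit-scaled series. Both
defaults are package choices, exposed as parameters.

A degenerate (constant) signal has no min–max scale and no quantile bins;
both operations raise instead of guessing.

### Classifier

ViT-style tokenization: the image is cut into non-overlapping
`patch_size × patch_size` patches (default 8), each linearly embedded to
`hidden_size` (default 32) with a learned positional embedding. The encoder
stack (default 3 layers) applies multi-head scaled dot-product attention
(`softmax(QKᵀ/√d_k)V`, 2 heads), residual Add&Norm, and a feed-forward
block of width `4 × hidden_size` (the feed-forward multiple is a package
choice). The decoder stack (default 3 layers) is driven by a single
learned class-query token: its self-attention is degenerate over one token
but retained for structural symmetry with the encoder; cross-attention
reads the encoder memory; a final linear + softmax yields class
probabilities. A single query token is the natural encoder–decoder reading
of image *classification* (one categorical output), and keeps the decoder's
train/predict contract identical to the CNN's.

Training uses Adam (lr `1e-3`), a multiplicative per-epoch learning-rate
decay of 0.97, batch size 256, dropout 0.5, and cross-entropy loss (the
loss is a package choice). The model returned is the one with the best
validation accuracy, ties resolved toward the later epoch. All parameter
initialization and batch shuffling derive from the config seed.

The ablation variant replaces the Transformer with four 3×3 convolution
blocks (16/32/64/64 channels, ReLU, 2×2 max-pool) followed by linear +
softmax; it is a config flip (`arch="cnn"`), not a separate code path, so
comparisons isolate the architecture.

Both networks run on an in-package reverse-mode autodiff engine
(`_autograd.py`) over numpy arrays. Its analytic gradients are verified
against central finite differences in the test suite for both
architectures. The engine keeps the package dependency-light and fully
deterministic on CPU.

Classical baselines consume the statistical feature vector (length, mean,
population std, min, max, median, skewness, excess kurtosis; the latter
two defined as 0 for constant signals) through scikit-learn learners;
their internals are not re-implemented here.

## Synthetic data

The generator emulates the two study conditions at desk scale:

* **analyte** — class `k` of `K` has baseline `b_k = 0.15 + 0.7k/(K−1)`
  and a square-pulse dwell of depth `(0.25 + 0.5k/(K−1))·b_k` over a
  class-dependent fraction of the record, position jittered ±20%; record
  lengths are uniform on 200–2000 samples (real events can be far longer,
  but the S2I module is length-agnostic, so reduced scale loses no
  coverage). Baselines are strictly ordered and spaced so classes are
  essentially Bayes-separable at noise σ ≤ 0.05. The templates are
  stylized synthetic stand-ins, not fits to instrument data.
* **barcode** — flat baseline 0 with raised half-cosine peaks of amplitude
  1 (half-width 3.5% of the record): a start peak at 8%, three identity
  bit slots at 26/44/62% (peak present iff the bit is 1), an end peak at
  80%, each center jittered ±5% so classifiers must read the pattern, not
  absolute positions; codes "000"–"111". Records can be right-padded with
  N(0, 0.072) noise to a fixed length (e.g. 700), matching the average
  noise level convention for short sequences.

A threshold peak-reading oracle (excursions above `baseline + max(3σ, 0.3)`;
first/last excursions anchor the span, bits read at quarters of it)
classifies ≥ 99% of σ = 0.02 barcodes. This certifies the synthetic task is
solvable *before* any learned model is evaluated on it, and gives the tests
an oracle independent of the networks.

What the generator does **not** model: pore kinetics, dwell-time
distributions fitted to real events, 1/f and drift noise, basecaller-style
squiggle structure. Passing tests therefore demonstrate the correctness and
learnability of the pipeline, not instrument-grade accuracy.

## Evaluation and statistics

Reports carry accuracy, macro-averaged recall/F1 (macro chosen for
class-imbalance sensitivity; classes absent from the truth are excluded),
the confusion matrix, per-class accuracies, and micro-averaged ROC/PR
curves (one-vs-rest indicator/score pairs pooled before thresholding).
Cross-validation is stratified k-fold (default 10), deterministic per seed.

Run vectors (per-fold accuracies) are compared by a Kolmogorov–Smirnov
test of each vector against a normal with that vector's sample mean and
standard deviation (estimated-parameter KS is a documented package choice),
accepting normality at P > .05, then a two-sided pooled-variance two-sample
t-test, declaring a significant difference at P < .05.

The strategy-comparison harness varies only the transform (RP/MTF/GASF/
GADF) across a single shared split, model and seed; the ablation harness
varies only the architecture. Both emit small tidy tables.

## Scaled-down reference study

The instrument datasets behind the published application are not publicly
deposited, so the package ships one fixed synthetic study
(`ts2inet.experiments`): barcode task, 8 classes × 125 records (100 train +
25 test via a stratified 0.8/0.2 split, with a stratified 12.5%
validation carve-out inside the training set), raw lengths 200–650, noise
σ = 0.05, GADF at 32 × 32, and a 1-encoder/1-decoder Transformer
(hidden 32, 2 heads). The small-sample schedule uses batch 32, dropout 0.1
and 20 epochs: the full-scale defaults (batch 256, dropout 0.5) are tuned
to datasets two orders of magnitude larger and would leave this 800-record
problem undertrained within the same epoch count. Patch size stays at 8
(16 tokens at 32 × 32). Under these conditions the Transformer reaches
≈ 0.99 test accuracy (chance 0.125), the CNN ablation ≈ 1.0, and GADF is
the strongest of the four strategies — consistent with the qualitative
ordering the method was designed around. MTF lags far behind on this task,
as expected for a transform that discards temporal-position information
the barcode classes depend on.

## Known limitations

* CPU-only numpy training: fine at desk scale, not for 10⁴⁺-record
  datasets.
* The S2I inversion recovers only the scaled series (and only for unit
  range); absolute amplitude is lost by design of min–max scaling.
* RP/MTF defaults (`ε`, bin count) are package choices, not tuned values.
* The synthetic generator's realism limits are listed above; no claim is
  made about accuracy on instrument data.
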