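# Methods

## Model

The classifier is a triplet network over parcel-level multispectral time
series. One shared encoder `f(.)` — a bidirectional LSTM, one layer of 128
hidden units per direction by default — maps a standardized `T x B` series
(T = 45 timesteps, B = 13 bands) to an embedding, defined as the
concatenation of the final hidden states of the forward and backward
passes (E = 256). A fully connected layer plus softmax turns the embedding
into class probabilities over the n = 13 crop classes. The three "branches"
of the triplet network are evaluations of this single parameter set on the
three triplet members; weight sharing is structural, not a synchronization
scheme.

Training minimizes, per triplet batch,

    L_t = L_c(x_p) + L_c(x_a) + L_c(x_n) + lambda * L_m(x_a, x_p, x_n)

with the weighted cross-entropy `L_c(x) = -w_c log p_c` (true class c) and
the margin hinge `L_m = max(0, D(a,p) - D(a,n) + m)` on non-squared
Euclidean embedding distances. Class weights are inverse median frequency,
`w_k = g~/g(k)`, computed on the training split only; the median-frequency
class has weight exactly 1. Defaults: margin m = 1.0, lambda = 1.0, Adam
with learning rate 0.001, batch size 256. These are the configuration at
which the method's published tuning found its optimum, and we keep them as
package defaults.

Batching convention: the per-triplet sum above is averaged over the batch,
i.e. the objective is (sum of the three branch-mean cross-entropies) +
lambda * (mean hinge). With lambda = 0 this equals 3x the plain mean
cross-entropy over the flattened member stream; the vanilla
`LSTMClassifier` exposes `objective_scale` so equivalence harnesses can
reproduce that factor exactly rather than relying on Adam's approximate
scale invariance.

## Triplet selection

* **Setup 1 (region-stratified):** anchors uniform over the training set;
  the negative is drawn from the anchor's region (different class), the
  positive from a different training region (same class). With more than
  two training regions the positive pool is all other regions. Requires
  every class present in at least two training regions; violations raise
  before training starts.
* **Setup 2 (naive):** positives same class, negatives different class,
  regions ignored.

Sampling is with replacement and there is no online hard-negative mining.
An epoch is one pass of `len(train)` triplets (one anchor draw per training
sample on average, configurable via `triplets_per_epoch`); the notion of an
epoch is a convention of this package, since triplet streams have no
natural finite length.

## Optimization details

* The encoder, backpropagation through time and Adam are implemented in
  NumPy. Gates follow the standard LSTM cell (input/forget/cell/output);
  parameters initialize uniform in (-1/sqrt(H), 1/sqrt(H)). Gradients are
  validated against central finite differences in float64.
* Arithmetic is float32 by default (the field's standard precision, and
  roughly twice the GEMM throughput of float64); `dtype` is configurable.
* **Input standardization.** Per-band z-scoring, fitted on the training
  split and stored with the model as a fixed affine input transform
  (`standardize_input=True`). Raw reflectances are all-positive and
  strongly correlated across bands, which conditions gradient descent
  poorly; standardizing them sharply accelerates convergence. This is an
  optimizer-side representation choice, not a radiometric correction of
  the data.
* The cross-entropy's log is clamped at 1e-12 when reported, so a
  confidently wrong prediction yields a large finite loss rather than
  -inf; gradients use the exact softmax/cross-entropy form, which needs no
  clamp. Zero-distance embedding pairs contribute zero gradient to the
  hinge (the subgradient choice at the non-differentiable point).
* Early stopping monitors plain classification accuracy of the validation
  samples (no triplets at validation), keeps the best checkpoint, and
  stops after `patience` epochs (default 5) without strict improvement.
  Argmax prediction ties break toward the lower class index.
* All randomness (initialization, triplet sampling, batch shuffling)
  derives from `random_state` through independent spawned streams, so runs
  are reproducible bit-for-bit in a fixed execution environment; exact
  float32 trajectories can differ in trailing digits across BLAS
  configurations.
* A non-finite training loss aborts with a diagnostic rather than
  continuing silently.

## Sequence standardization

Raw parcel series have variable length. Series longer than T are
subsampled at `round(i * (T_raw - 1) / (T - 1))` for i = 0..T-1 — evenly
spaced, always keeping the first and last observation, computed with an
exact integer product before the division so the chosen indices are
platform-independent. Shorter series are right-padded with zero rows and a
mask records observed steps; the default encoder consumes the zeros
directly (matching fixed-length plain-LSTM practice) and the mask is
carried for encoders that want it. How the reference corpus was reduced to
45 steps is not documented upstream; this rule is this package's choice.

## Synthetic data

The simulator emulates the statistical structure the method assumes, so
everything is testable without external downloads:

* **Seasonal profiles.** Each class gets per-band double-logistic curves
  `b + a [sigmoid((t - t0 + w)/r) - sigmoid((t - t0 - w)/f)]` — the
  canonical vegetation-phenology form — with seeded random parameters
  (baseline 0.05-0.25, amplitude 0.15-0.55 with occasional absorption
  bands, peak at 25-75% of the season). Reflectances are dimensionless in
  [0, ~1].
* **Confusable classes.** The group {fodder, permanent meadows, temporary
  meadows} shares base parameters with small offsets (sd 0.015 on
  baseline/amplitude, 1 timestep on peak), reproducing the inter-class
  similarity that motivates metric learning; in-group curve distances are
  strictly below all cross-group distances.
* **Imbalance.** Default class proportions follow the qualitative
  structure of real regional crop inventories (three dominant classes near
  17-24%, rare classes near 0.4%); counts are multinomial.
* **Regions.** 4 regions; each carries every class (forced during
  allocation whenever counts allow). A per-(region, class, band) smooth
  perturbation — offset plus one sinusoidal period, scaled by
  `region_shift_scale` (default 0.02 reflectance units) — creates the
  inter-region intra-class shift that setup 1 exploits.
* **Observation model.** Raw lengths uniform in 40-52 samples across the
  season; additive Gaussian noise (`noise_sd`, default 0.01) truncated at
  zero.

What the simulator does *not* emulate: clouds and atmospheric artifacts,
irregular acquisition calendars, mixed pixels/parcel boundary effects,
label noise, and realistic band correlation structure. Passing tests
therefore demonstrate the correctness and learning dynamics of the
machinery, not field-scale accuracy on real Sentinel-2 data.

The "easy" preset (`easy_config`: n = 5000, region shift 0.02, noise
0.01) is designed to be nearest-centroid separable (>= 0.95), so a sound
trainer should recover >= 0.9 validation accuracy within about ten epochs;
this bound is part of the test suite.

## Evaluation

Overall accuracy, Cohen's kappa, and macro (unweighted) means of per-class
precision/recall/f1 over all n classes; classes absent from the evaluated
sample contribute 0 to the macro means (conservative; per-class values are
emitted so other conventions are recomputable). "Mean f1" is the mean of
per-class f1 scores, not the f1 of mean precision/recall. Confusion
matrices come raw and column- (precision) and row- (recall) normalized.
The embedding diagnostic reports mean within-class pairwise distance, mean
between-class centroid distance, and their ratio (infinite when all
within-class points coincide).

## Problem sizes

Test-suite and acceptance-script runs use the simulator at n = 1200-5000
parcels with the default encoder (H = 128) or reduced variants (H = 16-64)
for fast unit checks; these sizes are chosen so the full suite runs on a
single CPU in minutes while still exercising the 13-class, 4-region,
45-step, 13-band geometry end to end. The multi-seed aggregation utility
(`multirun`) defaults to 5 runs with distinct seeds, reporting mean and
population standard deviation per metric.

## Known limitations

* No online (semi-)hard triplet mining within batches; selection is purely
  protocol-driven.
* The exact depth and normalization of the upstream bidirectional-LSTM
  reference architecture are not fully documented; depth is configurable
  (`num_layers`, default 1) rather than asserted.
* Masked (padded) timesteps are fed as zeros by default; a mask-aware
  encoder is out of scope.
* Training is single-CPU NumPy; it is intended for method study and
  desk-scale experiments, not for training on hundreds of thousands of
  parcels.
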