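# Methods

`popdecode` implements an encode-decode-classify pipeline for reading a
subject's multidimensional feature choice out of multi-channel neural
population activity, together with the synthetic task and recordings
needed to exercise every stage end to end. This note describes the
models and procedures, the parameters that matter, and the choices made
where the design was genuinely open.

## The task and its label space

The simulated task presents "quaddle" objects with four feature
dimensions — color, shape, pattern, arms — each having one *neutral*
value (index 0 by convention; grey / sphere / no pattern / straight
arms) and several non-neutral values. A legal object has between 1 and
3 non-neutral dimensions; the number of varying dimensions
(dimensionality, 1–3) is constant within a block of 25–50 trials, as
are the token gain/loss levels. Because every object has at least one
neutral dimension, neutral values dominate the class distribution of
every label — the central class-imbalance problem the metric and the
sampling scheme address.

A trial's decodable target is the chosen object's label: a 4-tuple of
feature-value indices. Covariates recorded per trial: outcome
(correct/error), gain level, loss level, learning status, previous
reward, dimensionality, session. The learning-status criterion is not
externally fixed; the generator flags the first `learning_trials`
(default 10) trials of a block as "learning", a free parameter.

## Synthetic recordings

Trial tensors are `channels x time x area-slot` arrays: 6 slots in
fixed order ACC, ACC, PFC, PFC, STR, STR; time in milliseconds with
the choice at t = 0, spanning [-1500, +1500] (3001 samples at 1 kHz);
the baseline window is the first 500 ms of the epoch. Desk-scale
defaults are 16 channels per slot (96 total); the paper-scale geometry
(64 per slot) is reachable through the same configuration fields.

The MUA-level generator draws Gaussian noise, smooths it with a 200 ms
Gaussian kernel (matching the smoothness of preprocessed multiunit
activity — throughout the package a "w ms Gaussian window" is a kernel
with sigma = w/6, i.e. the window covers +/-3 sigma), rescales to a
target SD, and adds the planted signal: for each feature dimension a
set of carrier channels whose mean shifts by `amplitude x value_index`
inside a configurable window (box or ramp profile). An `xor` encoding
is available for binary dimensions: the carriers split into two halves
whose signs agree for value 1 and disagree for value 0 with a random
per-trial sign, so no channel mean carries the label and only a
nonlinear readout can decode it.

The wideband generator produces spike-like biphasic ~1.5 kHz wavelets
at Poisson times (rate modulated by the planted features), optional
common-mode noise per probe and designated artifact channels, at a
configurable rate (default 12 kHz — enough to make the 0.75–5 kHz
band meaningful while staying desk-sized). What the generators do
*not* emulate: realistic spike waveforms and refractoriness,
behavioral (reinforcement-learning) choice dynamics, electrode drift,
and mains hum. Tests passing on this data show the pipeline's
correctness and its ability to recover planted structure, not
performance on real recordings.

## Preprocessing

Eight steps per probe: (1) bad-channel detection; (2) median
re-reference per probe-trial (median excludes masked channels); (3)
MUA extraction — 4th-order Butterworth band-pass 0.75–5 kHz applied
forward-backward, rectification, 4th-order low-pass 0.3 kHz, polyphase
resampling to 1 kHz, 200 ms Gaussian smoothing; (4) segmentation into
choice-aligned epochs with the 500 ms baseline; (5) removal of a
linear trend of baseline means across trials, per channel; (6)
z-normalization by session-wide baseline mean/SD (zero-SD channels are
masked); (7) regression screening; (8) stacking per-probe matrices
into the area tensor, padding missing probes with fully masked slots.

**Bad-channel detection.** Each channel is summarized by its per-trial
means and variances; the standardized feature matrix is projected onto
the principal components explaining 95% of variance, and k-means
(squared Euclidean, 10 restarts) is run for every k in 2..C/2. A
channel is flagged if, in more than half of the clusterings, it sits
in a singleton cluster or shares a cluster with a known artifact
channel. The consensus rule alone flags the most isolated channel of
*any* homogeneous probe about half the time (the most isolated point
of an isotropic cloud is a singleton at most k), so singleton votes
additionally require the channel to be a genuine feature-space outlier
(median/MAD distance z-score > 3.5). True artifacts (e.g. 10x
variance) pass this gate trivially; the gate only suppresses false
positives on homogeneous probes.

**Regression screening.** Per channel and time point, MUA across
trials is regressed on the task design (intercept, outcome, learned,
two dimensionality indicators, gain, loss, previous reward; constant
or collinear columns dropped). Whole-model significance is an F-test
at alpha = 0.05; a channel is retained iff some contiguous run of >=
50 significant milliseconds exists. Model-level (not per-coefficient)
significance is used, and no multiple-testing correction is applied
across time — the run-length rule is the intended false-positive
control. Note its limit: after 200 ms smoothing, null false positives
arrive in smoothing-width stretches, so the rule is liberal on smoothed
data; the package keeps the rule as specified and the tests check the
calibration of the underlying F-test instead.

## Hierarchical stratified sampling

Trials are grouped by recursively refining on a ranked covariate list:
labelset (the 4-tuple of chosen values), areas recorded in the
session, outcome, gain/loss, learning status, session. A group
refines only while it holds strictly more trials than folds (10);
terminal groups get unique labels. Each group's members are then
scattered over distinct folds in random order (groups larger than the
fold count wrap round-robin after a reshuffle). Folds rotate into
80/10/10 train/validation/test splits.

A known property: because the method is combination-based (strata are
labelsets, refined by covariates) and scatter within a group is
random, per-fold counts of an individual feature *value* fluctuate
like sqrt(count) — about +/-5 for a class with 300 instances in a
500-trial set. Tightening this would require marginal (per-value)
iterative stratification, a different algorithm that is deliberately
out of scope; the relevant guarantee kept here is that same-group
trials always land in distinct folds and stratified splits dominate
naive random splits on per-fold proportion deviation.

## Metric

All accuracy reporting uses balanced accuracy — the mean of per-class
recalls — extended to multiple labels by averaging over the M
dimensions, then affinely rescaled so a chance decoder maps to 0 and a
perfect one to 1. The chance decoder is any label-independent decoder;
its balanced accuracy is 1/N_j per dimension (mean of 1/N_j across
dimensions for the multi-label chance), which is what makes the
correction stable under class imbalance. Classes with zero support in
an evaluation set are dropped from the recall mean (logged) rather
than scored as recall 0, so a fold that happens to lack a rare class
is not penalized. Dummy classifiers (most-frequent, stratified)
operationalize chance empirically.

Time courses report the per-window scaled balanced accuracy per fold
with a t-interval across folds. Two peak definitions exist in the
field's usage: the maximum over windows of the across-fold mean
(default here, used for all single-value reports) and the mean over
folds of each fold's own maximum (available via
`AccuracyTimecourse.peak("mean_of_max")`; it is never smaller than the
default).

## Network

Input: trial tensors cut into S sliding windows of width W (default
500 ms, stride 250 ms; S = floor((T-W)/stride)+1). In the video
analogy, channels and within-window time are spatial axes, the area
slot is the image channel, and s is frame time. Windows are
optionally mean-binned along time (`time_bin_ms`, default 25) before
entering the network — a desk-scale compression that preserves the
signal band (everything above ~20 Hz is already removed by the 200 ms
smoothing).

The encoder is a stack of blocks with halving unit counts whose final
dense layer has 2L units (latent mean and log-variance); a bottleneck
of `bottleneck_depth` linear 2L-to-2L layers follows (linear, because
a ReLU here would constrain the log-variance to be nonnegative). The
latent is sampled by reparameterization, Z = mu + sigma * eps. The
decoder mirrors the encoder from an initial dense layer on Z. One
classifier head per feature dimension reads the encoder output (the 2L
bottleneck vector, deterministic at prediction time) and emits a
softmax over that dimension's values per window.

Block families: feedforward (dense, dropout, layer norm, ReLU), GRU
and LSTM (recurrent over the window sequence; within-window axes are
flattened per step), convolutional (kernel 30% of the channel x time
image, dropout, leaky ReLU, layer norm over channels, 2x2 max-pool
stride 2; the decoder upsamples with stride-2 transposed convolution
and crops to the encoder's sizes), resnet (convolutional plus a
stride-2 convolution skip path added after the pool), and multifilter
(three parallel convolutional paths with 20/30/40% kernels,
concatenated). Layer normalization is used throughout because batch
statistics are unstable at desk-scale batch sizes. Dropout defaults
to 0.2 in the full configuration (0.1 in the bundled demo).

The networks run on a small reverse-mode automatic-differentiation
engine written on numpy (`autodiff.py`): tensors record a dynamic
graph; convolution, transposed convolution and pooling use im2col.
Gradients are verified against central finite differences in the test
suite, and every family passes an overfit-one-batch check.

## Training

The loss is `L = lambda_r L_r + lambda_c L_c + lambda_KL L_KL`: masked
mean-squared reconstruction error (masked channels contribute exactly
zero), class-weighted cross-entropy summed over dimensions (weights =
inverse class frequency, normalized to mean 1), and the closed-form
Gaussian KL to the standard normal. At each epoch start the effective
weights are reset from the first iteration's component losses as
`lambda_i = omega_i / L_i(prior)`, which holds the weighted components
at the ratio of the weight factors omega (default 1 : 1 : 0.1); the
product form `omega_i * L_i(prior)` is available behind
`printed_lambda_rule` but does not maintain that ratio.

Before training, the whole tensor stack is normalized in four steps:
per-channel z-score, global min-max to [-1, 1], recenter to global
mean 0, rescale to global SD 0.25 (masked channels zeroed and excluded
from all statistics). Training-time augmentation adds, per channel, a
constant offset ~ N(0, 0.3^2), white noise ~ N(0, 0.15^2) and a random
walk of N(0, 0.007^2) increments, summed and smoothed with a 50 ms
Gaussian window so the added noise shares the data's frequency content
(the walk runs along each trial's concatenated window time).

The learning rate ramps linearly from 0 over epochs 1–5 and decays by
90% every 30 epochs. Gradients are accumulated over sub-batches
(weighted by sub-batch size, so the sum equals the full-batch
gradient), L2-clipped at norm 100 per network component (encoder,
decoder, classifier), and applied with ADAM (default; SGD available)
plus L2 regularization. Model selection keeps the epoch with the
highest peak validation scaled balanced accuracy over windows; ties go
to the earlier epoch.

## Interpreter

Per-dimension argmax (ties toward the lower index, so neutral wins a
tie) can produce an illegal object: all four dimensions neutral, or
all four non-neutral. Repair uses the neutral confidence (neutral
probability minus the best non-neutral probability, the max over
non-neutral values): an all-neutral label flips the dimension with the
lowest neutral confidence to its best non-neutral value; too many
non-neutral flips the non-neutral dimension with the highest neutral
confidence to neutral; repeated until legal. Each flip moves the
non-neutral count toward the legal band, so the procedure terminates;
it is idempotent and never touches a legal label. Repair applies to
the 4-dimension quaddle label space; evaluation on other label spaces
uses the plain argmax.

## Importance analysis

Channel importance is measured by zeroing channels at the network
input (after normalization — identical to masked-channel semantics)
and re-evaluating held-out accuracy. Strategies: *random* (at each
removal count r, the worst of `n_combos` random subsets; 500 at full
scale, fewer at desk scale), *ranked* (cumulative removal in order of
single-removal accuracy drop, ties toward the lower channel id) and
*sequential* (greedy forward construction minimizing peak accuracy at
each step; quadratic cost, capped by `max_r`). Peak accuracy inside
ablation is the max-of-fold-mean definition; evaluation uses each
fold's own test set. Area scores average, over r, each area's removed
fraction minus the equal-removal expectation r/n_channels; areas whose
channels leave earlier score higher. Sequential removal captures
joint (redundant) coding: removing one of a redundant carrier pair
costs nothing, so greedy removal prefers channels with individual
effects first and achieves peak accuracies at or below the ranked
strategy at matched r.

## Baselines

Two linear comparators share the exact evaluation stack (same folds,
same metric): a class-weighted multinomial logistic regression per
dimension on window-flattened features (time-averaged features behind
a flag), and a PCA-latent variant that projects onto the components
reaching a cumulative explained-variance target before the same linear
heads. A full-variance PCA is a lossless rotation, under which the
L2-regularized linear decoder is unchanged — the property that pins
the heads as linear. On linearly-coded signals both baselines match;
on the XOR code both sit at chance while the autoencoder model, whose
classifier reads a nonlinearly encoded latent, decodes well above it.

## Problem sizes and numerical choices

Desk-scale runs used throughout the tests: 600 trials of 16 x 6
channels at the full 3001-sample epoch for parameter recovery
(windows 500/250, time bin 25 ms, GRU with first layer 64 and latent
16, 10 epochs); 320 trials of 16 x 6 channels at 601 samples for the
XOR comparison (10 fold rotations); 320 trials of 8 x 6 channels for
the ablation recovery (removal counts 4/8/12, 150 random combinations,
greedy capped at 12). The synthetic generators default to amplitude 3
z-units on 8 carrier channels per dimension over noise SD 1 — a
strong but not trivial planted signal (single-channel d' ~ 3 before
windowing). Tolerances: normalization statistics to 1e-10 (float64);
float32 tensor storage is available for large runs, with normalization
statistics still accumulated in float64. Degenerate inputs: all-equal
channels produce no bad-channel flags (warning); constant channels are
masked at z-normalization; single-class training dimensions fall back
to constant heads; zero prior losses carry the previous lambda.

## Known limitations

The synthetic data cannot establish real-data decoding accuracy; the
planted-signal recovery shows correctness of the pipeline, not
biological plausibility. The run-length screening rule is liberal on
smoothed data (above). Per-fold feature-value balance is sqrt-of-count
at combination-based stratification (above). The hyperparameter sweep
harness exposes the full grid (family, depth, width, batch, classifier,
bottleneck, window, stride) but the full grid itself is not re-run; the
bundled defaults (GRU family, latent 500 at full scale) are declared,
not swept.
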