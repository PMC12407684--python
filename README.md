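# popdecode

Decoding of multidimensional feature choices from multi-channel neural
population activity: a complete encode–decode–classify pipeline with
synthetic task data, so every stage is testable end to end on a desk.

## The problem

In a value-based feature-learning task, a subject chooses among
"quaddle" objects defined over four feature dimensions (color, shape,
pattern, arms), each with one neutral and several non-neutral values;
legal objects have 1–3 non-neutral dimensions. Decoding the chosen
object from population recordings in ACC, PFC and striatum is a
*multi-label multi-class* problem with heavy class imbalance: every
object has at least one neutral dimension, so neutral values dominate
every label.

The package addresses the full chain:

1. **synth** — task metadata and channels × time × area-slot activity
   tensors with planted, dimension-specific signals (ground truth for
   parameter recovery); optional wideband traces for the preprocessing
   stage.
2. **preprocess** — bad-channel detection (PCA + k-means consensus),
   median re-referencing, multiunit-activity extraction (band-pass
   0.75–5 kHz → rectify → low-pass 0.3 kHz → 1 kHz → 200 ms Gaussian
   smoothing), choice-aligned segmentation, baseline detrending,
   z-normalization, task-modulation screening, area-tensor assembly.
3. **strata** — hierarchical stratified sampling into 10 folds
   (labelset → areas → outcome → gain/loss → learning status →
   session) with 80/10/10 train/validation/test rotations.
4. **model / train** — a gated-recurrent variational autoencoder over
   sliding windows of the trial tensor, with one classifier head per
   feature dimension; alternative block families (feedforward, LSTM,
   convolutional, ResNet, multi-filter); three-component loss with
   adaptive weighting, ramp/decay learning-rate schedule, gradient
   accumulation and per-component clipping. The networks run on a
   small numpy reverse-mode autodiff engine included in the package.
5. **metrics / interpret** — chance-corrected balanced accuracy and a
   legality interpreter that repairs impossible quaddle predictions.
6. **importance** — channel-ablation analysis (random, ranked,
   sequential removal) with area-level summaries.
7. **baselines** — logistic-regression and PCA-latent comparators on
   the identical evaluation stack.

## The metric

All accuracy is *scaled balanced accuracy*. With M feature dimensions
and N_j values in dimension j,

    BA_j = (1/N_j) Σ_i TP_ij / (TP_ij + FN_ij)        (mean class recall)
    BA   = (1/M) Σ_j BA_j                             (multi-label mean)
    BA~  = (BA − BA_c) / (1 − BA_c),   BA_c = (1/M) Σ_j 1/N_j

so any label-independent (chance) decoder scores 0 and a perfect
decoder scores 1, regardless of class imbalance. A most-frequent dummy
on 90/10 binary labels has plain accuracy 0.9 but BA exactly 0.5.

## Worked example

The bundled demo configuration simulates ~115 trials (16 channels × 6
area slots, 3001 ms epochs) with an amplitude-3 signal planted into six
carrier channels per feature dimension, stratifies into 10 folds,
trains the GRU autoencoder for 6 epochs on two fold rotations, and
evaluates the held-out test folds:

```bash
popdecode run --outdir demo_run --seed 1
```

prints (abridged):

```json
{
  "overall":        {"peak": 0.227, "peak_time_ms": 750.0},
  "dimensionality": {"1": {"peak": 0.445}, "2": {"peak": 0.344}},
  "baseline_logistic":   {"peak": 0.569},
  "baseline_pca_latent": {"peak": 0.547}
}
```

Reading this: the decoder reaches a peak scaled balanced accuracy of
0.23 on held-out trials — 0 would be chance, 1 perfect — peaking 750 ms
after the choice, and decodes 1-dimensional blocks (0.45) better than
2-dimensional ones (0.34), the expected difficulty ordering. On this
*linearly* coded demo signal the linear baselines outperform the
briefly-trained autoencoder; the autoencoder's advantage appears on
nonlinear codes (see the XOR comparison in `tests/test_acceptance.py`,
where the linear baselines drop to chance and the autoencoder does
not). The run directory also contains `metrics.csv` (per fold and
window), `folds.csv`, the dataset HDF5 and a JSONL log.

Library use mirrors the CLI; see `popdecode.synth`, `popdecode.train.fit`
and `popdecode.importance` docstrings, and `docs/methods.md` for the
model, parameter and design details.

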