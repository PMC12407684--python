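"""Chance-corrected balanced accuracy for multi-label multi-class decoding.

The choices to decode have M feature dimensions (labels), each with
N_j possible values (classes, one of them the neutral value).  Because
neutral values dominate the class distribution, plain accuracy is
misleading; all evaluation here uses balanced accuracy — the mean of
per-class recalls — extended to multiple labels by averaging over
dimensions, and affinely rescaled so that a label-independent (chance)
decoder scores 0 and a perfect decoder scores 1:

    BA_j  = (1/N_j) sum_i TP_ij / (TP_ij + FN_ij)
    BA    = (1/M) sum_j BA_j
    BA~   = (BA - BA_chance) / (1 - BA_chance)

The chance decoder is any label-independent decoder; its balanced
accuracy is 1/N_j per dimension regardless of the class priors, which
is what makes the rescaling stable under class imbalance.  Dummy
classifiers (most-frequent and stratified) operationalize chance
empirically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("popdecode.metrics")


# ---------------------------------------------------------------------------
# Confusion counts
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """Per-dimension confusion matrices (rows: true class, cols: predicted)."""

    matrices: list[np.ndarray]

    @property
    def n_dimensions(self) -> int:
        return len(self.matrices)


def confusion_from_predictions(
    labels: np.ndarray, predictions: np.ndarray, dim_sizes: list[int]
) -> ConfusionCounts:
    """Build confusion counts from (n, M) integer label/prediction arrays."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have identical shape")
    mats = []
    for j, nj in enumerate(dim_sizes):
        m = np.zeros((nj, nj), dtype=int)
        np.add.at(m, (labels[:, j], predictions[:, j]), 1)
        mats.append(m)
    return ConfusionCounts(mats)


def balanced_accuracy(confusion: ConfusionCounts, dimension: int) -> float:
    """Mean of per-class recalls for one dimension.

    Classes with zero support in the fixture are excluded from the mean
    (and logged) rather than counted as recall 0, so a fold that happens
    to lack a rare class is not penalized for it.
    """
    m = confusion.matrices[dimension]
    support = m.sum(axis=1)
    present = support > 0
    if not present.any():
        raise ValueError("balanced accuracy undefined: all class supports are zero")
    if not present.all():
        logger.info(
            "dimension %d: dropping zero-support classes %s from recall mean",
            dimension,
            np.flatnonzero(~present).tolist(),
        )
    recalls = np.diag(m)[present] / support[present]
    return float(recalls.mean())


def multilabel_balanced_accuracy(confusion: ConfusionCounts) -> float:
    """Unweighted mean of per-dimension balanced accuracies."""
    if confusion.n_dimensions < 1:
        raise ValueError("need at least one dimension")
    return float(
        np.mean([balanced_accuracy(confusion, j) for j in range(confusion.n_dimensions)])
    )


def chance_ba(dim_sizes: list[int]) -> float:
    """Balanced accuracy of any label-independent decoder: mean of 1/N_j."""
    if any(n < 2 for n in dim_sizes):
        raise ValueError("every dimension needs >= 2 classes")
    return float(np.mean([1.0 / n for n in dim_sizes]))


def scaled_balanced_accuracy(ba: float, ba_chance: float) -> float:
    """Affine chance correction: chance -> 0, perfect -> 1."""
    if ba_chance >= 1.0:
        raise ValueError("chance balanced accuracy must be < 1")
    return (ba - ba_chance) / (1.0 - ba_chance)


def scaled_ba_from_predictions(
    labels: np.ndarray, predictions: np.ndarray, dim_sizes: list[int]
) -> float:
    conf = confusion_from_predictions(labels, predictions, dim_sizes)
    return scaled_balanced_accuracy(multilabel_balanced_accuracy(conf), chance_ba(dim_sizes))


# ---------------------------------------------------------------------------
# Dummy classifiers
# ---------------------------------------------------------------------------


@dataclass
class DummyClassifier:
    """Label-independent baseline: most-frequent class or stratified draws."""

    kind: str = "most_frequent"  # or "stratified"
    frequencies_: list[np.ndarray] | None = None

    def fit(self, labels: np.ndarray, dim_sizes: list[int]) -> "DummyClassifier":
        labels = np.asarray(labels)
        self.frequencies_ = [
            np.bincount(labels[:, j], minlength=nj) / labels.shape[0]
            for j, nj in enumerate(dim_sizes)
        ]
        return self

    def predict(self, n: int, seed: int = 0) -> np.ndarray:
        if self.frequencies_ is None:
            raise RuntimeError("fit first")
        rng = np.random.default_rng(seed)
        cols = []
        for freq in self.frequencies_:
            if self.kind == "most_frequent":
                cols.append(np.full(n, int(freq.argmax())))
            elif self.kind == "stratified":
                cols.append(rng.choice(freq.size, size=n, p=freq))
            else:
                raise ValueError(f"unknown dummy kind {self.kind!r}")
        return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# Accuracy over time
# ---------------------------------------------------------------------------


@dataclass
class AccuracyTimecourse:
    """Scaled balanced accuracy per window, summarized across folds."""

    per_fold: np.ndarray  # (n_folds, S)
    mean: np.ndarray  # (S,)
    ci_low: np.ndarray
    ci_high: np.ndarray
    window_times_ms: np.ndarray

    def peak(self, definition: str = "max_of_mean") -> tuple[float, float]:
        """(peak scaled BA, time of peak).

        ``max_of_mean``: maximum over windows of the across-fold mean
        (the default, used for single-value reports); ``mean_of_max``:
        mean over folds of each fold's own maximum (time is then the
        time of the peak of the fold mean).
        """
        if definition == "max_of_mean":
            idx = int(self.mean.argmax())
            return float(self.mean[idx]), float(self.window_times_ms[idx])
        if definition == "mean_of_max":
            idx = int(self.mean.argmax())
            return float(self.per_fold.max(axis=1).mean()), float(self.window_times_ms[idx])
        raise ValueError(f"unknown peak definition {definition!r}")


def accuracy_timecourse(
    fold_predictions: list[np.ndarray],
    fold_labels: list[np.ndarray],
    dim_sizes: list[int],
    window_times_ms: np.ndarray,
    confidence: float = 0.95,
) -> AccuracyTimecourse:
    """Per-window scaled balanced accuracy with a t-interval over folds.

    ``fold_predictions[f]`` has shape (n_f, S, M); ``fold_labels[f]``
    has shape (n_f, M).  All folds must share the same window grid.
    """
    window_times_ms = np.asarray(window_times_ms, dtype=float)
    n_windows = window_times_ms.size
    for p in fold_predictions:
        if p.shape[1] != n_windows:
            raise ValueError("window grids differ between folds")
    chance = chance_ba(dim_sizes)
    per_fold = np.empty((len(fold_predictions), n_windows))
    for f, (preds, labels) in enumerate(zip(fold_predictions, fold_labels)):
        for s in range(n_windows):
            conf = confusion_from_predictions(labels, preds[:, s, :], dim_sizes)
            per_fold[f, s] = scaled_balanced_accuracy(
                multilabel_balanced_accuracy(conf), chance
            )
    mean = per_fold.mean(axis=0)
    n_folds = per_fold.shape[0]
    if n_folds > 1:
        sem = per_fold.std(axis=0, ddof=1) / np.sqrt(n_folds)
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=n_folds - 1)
        half = tcrit * sem
    else:
        half = np.zeros(n_windows)
    return AccuracyTimecourse(
        per_fold=per_fold,
        mean=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        window_times_ms=window_times_ms,
    )


def timecourse_frame(tc: AccuracyTimecourse) -> "pd.DataFrame":
    """Long-format report: one row per (fold, window)."""
    import pandas as pd

    rows = []
    for f in range(tc.per_fold.shape[0]):
        for s, t in enumerate(tc.window_times_ms):
            rows.append(
                {
                    "fold": f,
                    "window": s,
                    "time_ms": float(t),
                    "scaled_ba": tc.per_fold[f, s],
                }
            )
    return pd.DataFrame(rows)


def summarize_by_splits(
    fold_predictions: list[np.ndarray],
    fold_labels: list[np.ndarray],
    fold_covariates: list["pd.DataFrame"],
    dim_sizes: list[int],
    window_times_ms: np.ndarray,
    split_columns: tuple[str, ...] = ("dimensionality", "learned", "outcome"),
) -> dict:
    """Peak scaled BA overall and per trial-variable split.

    Splits with too few trials to cover a class are skipped for the
    affected level (the zero-support handling of balanced accuracy
    applies within the remaining classes).
    """
    out: dict = {}
    tc = accuracy_timecourse(fold_predictions, fold_labels, dim_sizes, window_times_ms)
    peak, peak_time = tc.peak()
    out["overall"] = {"peak": peak, "peak_time_ms": peak_time}
    for col in split_columns:
        levels = sorted(
            set().union(*[set(cov[col].unique()) for cov in fold_covariates])
        )
        out[col] = {}
        for level in levels:
            preds, labels = [], []
            for fp, fl, cov in zip(fold_predictions, fold_labels, fold_covariates):
                sel = (cov[col] == level).to_numpy()
                if sel.sum() == 0:
                    continue
                preds.append(fp[sel])
                labels.append(fl[sel])
            if not preds:
                continue
            try:
                tcl = accuracy_timecourse(preds, labels, dim_sizes, window_times_ms)
                p, t = tcl.peak()
                out[col][str(level)] = {"peak": p, "peak_time_ms": t}
            except ValueError:
                logger.info("split %s=%s skipped (undefined balanced accuracy)", col, level)
    return out
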