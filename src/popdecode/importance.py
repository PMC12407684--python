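"""Channel-ablation importance analysis for a trained decoder.

Importance of an input channel is measured by zeroing it at the network
input (after dataset normalization, matching the semantics of masked
channels) and re-evaluating the decoder.  Three removal strategies are
provided:

* random: at each removal count r, test ``n_combos`` random channel
  subsets and keep the one with the lowest peak accuracy;
* ranked: rank channels by the accuracy drop caused by their individual
  removal, then remove cumulatively in rank order;
* sequential: greedy forward construction — at each step add the
  channel whose removal (together with those already removed) lowers
  the peak accuracy the most.

Peak accuracy is the maximum over time windows of the across-fold mean
of the scaled balanced accuracy.  Area-level summaries compare the
fraction of removed channels per recording area with the equal-removal
line (removing the same fraction from every area): an area whose
channels are removed earlier than equal share scores higher.

Channels are addressed by flat ids ``slot * C + channel`` over the
channels x area-slot grid; only unmasked channels participate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import interpret, metrics
from .synth import AREA_LABELS


@dataclass
class EvalData:
    """Per-fold held-out data sharing one window grid."""

    folds: list[tuple[np.ndarray, np.ndarray]]  # (windows, labels) per fold
    dim_sizes: list[int]
    window_times_ms: np.ndarray


@dataclass
class AblationResult:
    strategy: str
    removal_counts: list[int] = field(default_factory=list)
    removed_sets: list[list[int]] = field(default_factory=list)
    peaks: list[float] = field(default_factory=list)
    peak_times: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "r": self.removal_counts,
                "removed_ids": [" ".join(map(str, s)) for s in self.removed_sets],
                "peak_ba": self.peaks,
                "peak_time": self.peak_times,
            }
        )


def channel_ids(channel_mask: np.ndarray) -> np.ndarray:
    """Flat ids (slot * C + channel) of the unmasked channels."""
    c, a = channel_mask.shape
    grid = np.arange(c * a).reshape(a, c).T  # id = slot * C + channel
    return np.sort(grid[channel_mask])


def zero_channels(windows: np.ndarray, channels, n_channels: int) -> np.ndarray:
    """Zero the listed flat channel ids in (n, S, C, Wb, A) windows."""
    out = windows.copy()
    for ch in channels:
        slot, c = divmod(int(ch), n_channels)
        if not (0 <= c < windows.shape[2] and 0 <= slot < windows.shape[4]):
            raise ValueError(f"unknown channel id {ch}")
        out[:, :, c, :, slot] = 0.0
    return out


def ablate(predictors, data: EvalData, channels) -> tuple[float, float, np.ndarray]:
    """Evaluate with the listed channels zeroed.

    ``predictors``: one predictor per fold (an object with
    ``predict_proba``).  Returns (peak, peak_time, mean curve over folds).
    """
    n_channels = data.folds[0][0].shape[2]
    per_fold = []
    repair = len(data.dim_sizes) == 4
    chance = metrics.chance_ba(data.dim_sizes)
    for predictor, (windows, labels) in zip(predictors, data.folds):
        ablated = zero_channels(windows, channels, n_channels)
        probs = predictor.predict_proba(ablated)
        if repair:
            preds = interpret.decode_batch(probs)
        else:
            preds = np.stack([p.argmax(axis=-1) for p in probs], axis=-1)
        scores = []
        for s in range(preds.shape[1]):
            conf = metrics.confusion_from_predictions(labels, preds[:, s, :], data.dim_sizes)
            scores.append(
                metrics.scaled_balanced_accuracy(
                    metrics.multilabel_balanced_accuracy(conf), chance
                )
            )
        per_fold.append(scores)
    mean_curve = np.mean(per_fold, axis=0)
    idx = int(mean_curve.argmax())
    return float(mean_curve[idx]), float(data.window_times_ms[idx]), mean_curve


def random_removal(
    predictors,
    data: EvalData,
    removal_counts,
    channel_mask: np.ndarray,
    n_combos: int = 500,
    seed: int = 0,
) -> AblationResult:
    """Minimum-over-combinations peak accuracy per removal count."""
    rng = np.random.default_rng(seed)
    ids = channel_ids(channel_mask)
    result = AblationResult("random")
    for r in removal_counts:
        if r > ids.size:
            raise ValueError(f"cannot remove {r} of {ids.size} channels")
        best = (np.inf, None, None)
        combos = (
            [ids.tolist()]
            if r == ids.size
            else [sorted(rng.choice(ids, size=r, replace=False).tolist()) for _ in range(n_combos)]
        )
        seen = set()
        for combo in combos:
            key = tuple(combo)
            if key in seen:
                continue
            seen.add(key)
            peak, t, _ = ablate(predictors, data, combo)
            if peak < best[0]:
                best = (peak, t, combo)
        result.removal_counts.append(int(r))
        result.removed_sets.append(list(best[2]))
        result.peaks.append(best[0])
        result.peak_times.append(best[1])
    return result


def single_removal_drops(predictors, data: EvalData, channel_mask: np.ndarray):
    """Peak-accuracy drop of each channel's individual removal."""
    ids = channel_ids(channel_mask)
    baseline, _, _ = ablate(predictors, data, [])
    drops = {}
    for ch in ids:
        peak, _, _ = ablate(predictors, data, [ch])
        drops[int(ch)] = baseline - peak
    return baseline, drops


def ranked_removal(
    predictors, data: EvalData, channel_mask: np.ndarray, max_r: int | None = None
) -> AblationResult:
    """Cumulative removal in order of single-removal accuracy drop
    (ties broken toward the lower channel id)."""
    _, drops = single_removal_drops(predictors, data, channel_mask)
    order = sorted(drops, key=lambda ch: (-drops[ch], ch))
    if max_r is not None:
        order = order[:max_r]
    result = AblationResult("ranked")
    removed: list[int] = []
    for ch in order:
        removed.append(ch)
        peak, t, _ = ablate(predictors, data, removed)
        result.removal_counts.append(len(removed))
        result.removed_sets.append(list(removed))
        result.peaks.append(peak)
        result.peak_times.append(t)
    return result


def sequential_removal(
    predictors, data: EvalData, channel_mask: np.ndarray, max_r: int
) -> AblationResult:
    """Greedy forward construction of the most damaging removal set."""
    ids = list(channel_ids(channel_mask))
    if max_r > len(ids):
        raise ValueError("max_r exceeds the number of unmasked channels")
    result = AblationResult("sequential")
    removed: list[int] = []
    remaining = list(ids)
    for _ in range(max_r):
        best = (np.inf, None, None)
        for ch in remaining:
            peak, t, _ = ablate(predictors, data, removed + [ch])
            if peak < best[0]:
                best = (peak, t, ch)
        removed.append(best[2])
        remaining.remove(best[2])
        result.removal_counts.append(len(removed))
        result.removed_sets.append(list(removed))
        result.peaks.append(best[0])
        result.peak_times.append(best[1])
    return result


def area_summary(
    result: AblationResult,
    channel_mask: np.ndarray,
    area_labels: tuple[str, ...] = AREA_LABELS,
) -> dict[str, float]:
    """Mean (over removal counts) of each area's removed fraction relative
    to the equal-removal line.

    At removal count r the equal-removal expectation is r / n_channels of
    each area's channels; an area whose channels leave earlier scores
    above zero.
    """
    n_c = channel_mask.shape[0]
    ids = channel_ids(channel_mask)
    area_of = {int(ch): area_labels[int(ch) // n_c] for ch in ids}
    areas = sorted(set(area_of.values()))
    totals = {ar: sum(1 for ch in ids if area_of[int(ch)] == ar) for ar in areas}
    rel = {ar: [] for ar in areas}
    for r, removed in zip(result.removal_counts, result.removed_sets):
        expected = r / ids.size
        for ar in areas:
            got = sum(1 for ch in removed if area_of[int(ch)] == ar) / max(totals[ar], 1)
            rel[ar].append(got - expected)
    return {ar: float(np.mean(v)) for ar, v in rel.items()}
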