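"""Preprocessing of wideband recordings into normalized area-stacked tensors.

The pipeline mirrors standard multiunit-activity (MUA) preprocessing for
linear-probe recordings:

1.  bad-channel detection per probe (PCA features + k-means consensus);
2.  median re-referencing per probe and trial;
3.  MUA extraction: band-pass 0.75-5 kHz, rectification, low-pass
    0.3 kHz, resampling to 1 kHz, 200 ms Gaussian smoothing;
4.  segmentation into choice-aligned epochs (-1500..+1500 ms) with a
    500 ms baseline window at trial start;
5.  linear detrending of baseline means across trials;
6.  z-normalization per channel against session-wide baseline statistics;
7.  regression screening: channels without any >= 50 ms run of
    task-modulated time points (overall F-test at alpha = 0.05) are
    removed;
8.  stacking per-probe matrices into a channels x time x area tensor
    with slots ordered ACC, ACC, PFC, PFC, STR, STR; absent probes
    become fully masked slots.

Filters are 4th-order Butterworth applied forward-backward (zero
phase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .synth import (
    AREA_LABELS,
    BASELINE_SAMPLES,
    T_DEFAULT,
    TrialTensor,
    gaussian_window_sigma,
)

logger = logging.getLogger("popdecode.preprocess")

EPOCH_PRE_MS = 1500
EPOCH_POST_MS = 1500
SCREEN_ALPHA = 0.05
SCREEN_RUN_MS = 50


@dataclass
class ChannelScreenResult:
    """Per-channel screening flags with reason codes."""

    bad_artifact: np.ndarray  # (C,) bool — flagged by the cluster screen
    unmodulated: np.ndarray  # (C,) bool — flagged by the regression screen
    reason: list[str]

    @property
    def keep(self) -> np.ndarray:
        return ~(self.bad_artifact | self.unmodulated)

    def to_frame(self, probe: int = 0, area: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": np.arange(self.bad_artifact.size),
                "probe": probe,
                "area": area,
                "flag": ~self.keep,
                "reason": self.reason,
            }
        )


def _blank_screen(n_channels: int) -> ChannelScreenResult:
    return ChannelScreenResult(
        bad_artifact=np.zeros(n_channels, dtype=bool),
        unmodulated=np.zeros(n_channels, dtype=bool),
        reason=[""] * n_channels,
    )


# ---------------------------------------------------------------------------
# Step 1: bad-channel detection
# ---------------------------------------------------------------------------


def detect_bad_channels(
    trials: np.ndarray,
    known_artifacts: set[int] | None = None,
    seed: int = 0,
) -> ChannelScreenResult:
    """Consensus k-means screen for compromised channels.

    ``trials``: (n_trials, C, n_samples) wideband traces for one probe.
    Each channel is summarized by its per-trial mean and variance; the
    feature matrix is standardized and projected onto the principal
    components explaining 95% of variance.  For every k in 2..C/2 the
    channels are k-means clustered (squared Euclidean, 10 restarts); a
    channel lands on the bad list if, in more than half of the
    clusterings, it sits in a singleton cluster or shares a cluster with
    a known artifact channel.
    """
    known_artifacts = known_artifacts or set()
    n_trials, n_channels, _ = trials.shape
    if n_channels < 4:
        raise ValueError("need at least 4 channels on the probe")
    result = _blank_screen(n_channels)
    feats = np.concatenate([trials.mean(axis=2).T, trials.var(axis=2).T], axis=1)
    spread = feats.std(axis=0)
    if np.all(spread < 1e-12):
        logger.warning("all channels identical; bad-channel screen flags nothing")
        return result
    feats = (feats - feats.mean(axis=0)) / np.where(spread > 1e-12, spread, 1.0)
    n_comp = min(feats.shape[0] - 1, feats.shape[1])
    pca = PCA(n_components=n_comp, random_state=seed).fit(feats)
    keep = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), 0.95) + 1)
    proj = pca.transform(feats)[:, :keep]
    # robust outlier gate: on a homogeneous probe the most isolated channel
    # of an isotropic cloud ends up in a singleton cluster at most k, so a
    # singleton vote only counts for channels that are genuine feature-space
    # outliers (median/MAD distance z-score > 3.5)
    dist = np.linalg.norm(proj - np.median(proj, axis=0), axis=1)
    mad = np.median(np.abs(dist - np.median(dist)))
    zscore = (dist - np.median(dist)) / max(1.4826 * mad, 1e-12)
    is_outlier = zscore > 3.5
    ks = range(2, n_channels // 2 + 1)
    votes = np.zeros(n_channels, dtype=int)
    n_clusterings = 0
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + k).fit(proj)
        n_clusterings += 1
        counts = np.bincount(km.labels_, minlength=k)
        for c in range(n_channels):
            lab = km.labels_[c]
            singleton = counts[lab] == 1 and is_outlier[c]
            with_artifact = any(
                km.labels_[a] == lab for a in known_artifacts if a != c
            )
            if singleton or with_artifact:
                votes[c] += 1
    bad = votes > n_clusterings / 2
    result.bad_artifact = bad
    for c in np.flatnonzero(bad):
        result.reason[c] = "cluster_outlier"
    return result


# ---------------------------------------------------------------------------
# Step 2: median re-referencing
# ---------------------------------------------------------------------------


def median_rereference(trials: np.ndarray, channel_mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract the across-channel median per probe-trial and time point.

    Masked channels are excluded from the median and left untouched.
    """
    trials = np.asarray(trials, dtype=float)
    n_trials, n_channels, _ = trials.shape
    if channel_mask is None:
        channel_mask = np.ones(n_channels, dtype=bool)
    n_keep = int(channel_mask.sum())
    if n_keep == 0:
        raise ValueError("all channels masked; cannot re-reference")
    if n_keep < 3:
        raise ValueError("median re-referencing needs >= 3 unmasked channels")
    out = trials.copy()
    med = np.median(trials[:, channel_mask, :], axis=1, keepdims=True)
    out[:, channel_mask, :] -= med
    return out


# ---------------------------------------------------------------------------
# Step 3: MUA extraction
# ---------------------------------------------------------------------------


def extract_mua(trials: np.ndarray, fs_in: float, fs_out: float = 1000.0) -> np.ndarray:
    """Band-pass 0.75-5 kHz -> rectify -> low-pass 0.3 kHz -> resample to
    1 kHz -> smooth with a 200 ms Gaussian window.

    ``trials``: (..., n_samples) at ``fs_in``; returns (..., n_out).
    """
    if fs_in < 10_000:
        raise ValueError("input sampling rate must be >= 10 kHz")
    band = sps.butter(4, [750.0, 5000.0], btype="bandpass", fs=fs_in, output="sos")
    x = sps.sosfiltfilt(band, trials, axis=-1)
    x = np.abs(x)
    low = sps.butter(4, 300.0, btype="lowpass", fs=fs_in, output="sos")
    x = sps.sosfiltfilt(low, x, axis=-1)
    frac = Fraction(int(fs_out), int(fs_in))
    x = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    return gaussian_filter1d(x, gaussian_window_sigma(200) * fs_out / 1000.0, axis=-1)


# ---------------------------------------------------------------------------
# Steps 4-5: segmentation and detrending
# ---------------------------------------------------------------------------


def segment_and_detrend(
    mua: np.ndarray,
    choice_idx: int,
    trial_start_idx: int = 0,
    fs: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut choice-aligned epochs and remove the across-trial baseline trend.

    ``mua``: (n_trials, C, L) continuous MUA at 1 kHz, one row per trial
    recording; ``choice_idx``: sample of the choice within each trace.
    The epoch spans [-1500, +1500] ms around the choice (3001 samples);
    the baseline is the first 500 ms from ``trial_start_idx``.  Trials
    whose epoch exceeds the trace bounds are dropped (logged).  A linear
    trend of baseline means across trial index is fit per channel and
    subtracted from both the epoch and the baseline.

    Returns (epochs, baselines, kept_indices).
    """
    n_trials, n_channels, length = mua.shape
    pre = int(EPOCH_PRE_MS * fs / 1000)
    post = int(EPOCH_POST_MS * fs / 1000)
    base_len = int(BASELINE_SAMPLES * fs / 1000)
    lo, hi = choice_idx - pre, choice_idx + post + 1
    if trial_start_idx + base_len > length:
        raise ValueError("baseline window exceeds trace length")
    kept = []
    if lo < 0 or hi > length:
        logger.info("epoch [-%d,+%d] around sample %d exceeds bounds; all trials dropped", pre, post, choice_idx)
        raise ValueError("epoch exceeds recording bounds for every trial")
    kept = np.arange(n_trials)
    epochs = mua[:, :, lo:hi].copy()
    baselines = mua[:, :, trial_start_idx : trial_start_idx + base_len].copy()
    # per-channel linear trend of baseline means across trials
    base_means = baselines.mean(axis=2)  # (n_trials, C)
    idx = np.arange(n_trials, dtype=float)
    design = np.stack([np.ones(n_trials), idx], axis=1)
    coef, *_ = np.linalg.lstsq(design, base_means, rcond=None)  # (2, C)
    trend = design @ coef  # (n_trials, C)
    epochs -= trend[:, :, None]
    baselines -= trend[:, :, None]
    return epochs, baselines, kept


# ---------------------------------------------------------------------------
# Step 6: z-normalization
# ---------------------------------------------------------------------------


def znormalize(
    epochs: np.ndarray, baselines: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each channel by its session-wide baseline mean and SD.

    Channels with zero baseline SD cannot be scaled and are masked
    (logged).  Returns (epochs, baselines, valid_channel_mask).
    """
    mu = baselines.mean(axis=(0, 2))  # (C,)
    sd = baselines.std(axis=(0, 2))
    valid = sd > 1e-12
    if not valid.all():
        logger.info("masking %d constant channels (zero baseline SD)", int((~valid).sum()))
    safe_sd = np.where(valid, sd, 1.0)
    z_epochs = (epochs - mu[None, :, None]) / safe_sd[None, :, None]
    z_base = (baselines - mu[None, :, None]) / safe_sd[None, :, None]
    z_epochs[:, ~valid, :] = 0.0
    z_base[:, ~valid, :] = 0.0
    return z_epochs, z_base, valid


# ---------------------------------------------------------------------------
# Step 7: regression screening
# ---------------------------------------------------------------------------


def build_design(metadata: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Task-variable design matrix: intercept, outcome, learned, two
    dimensionality indicators, gain, loss, previous reward.

    Constant columns (no variation in the data) are dropped with a log
    entry so the matrix has full column rank.
    """
    cols = {
        "intercept": np.ones(len(metadata)),
        "x_reward": metadata["outcome"].to_numpy(float),
        "x_learned": metadata["learned"].to_numpy(float),
        "x_attention_2d": (metadata["dimensionality"] == 2).to_numpy(float),
        "x_attention_3d": (metadata["dimensionality"] == 3).to_numpy(float),
        "x_gain": metadata["gain"].to_numpy(float),
        "x_loss": metadata["loss"].to_numpy(float),
        "x_previous": metadata["previous_reward"].to_numpy(float),
    }
    names, arrays = ["intercept"], [cols["intercept"]]
    for name, arr in cols.items():
        if name == "intercept":
            continue
        if arr.std() < 1e-12:
            logger.info("dropping constant regressor %s", name)
            continue
        names.append(name)
        arrays.append(arr)
    X = np.stack(arrays, axis=1)
    # drop collinear columns, keeping the earlier ones
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
            keep.append(j)
        else:
            logger.info("dropping collinear regressor %s", names[j])
    return X[:, keep], [names[j] for j in keep]


def screen_task_modulated(
    epochs: np.ndarray,
    metadata: pd.DataFrame,
    alpha: float = SCREEN_ALPHA,
    run_ms: int = SCREEN_RUN_MS,
) -> ChannelScreenResult:
    """Flag channels with no >= 50 ms run of task-modulated time points.

    Per channel and time point, MUA across trials is regressed on the
    task design; model significance is an overall F-test at ``alpha``.
    A channel is retained iff some contiguous run of at least
    ``run_ms`` significant time points exists.
    """
    n_trials, n_channels, n_time = epochs.shape
    X, names = build_design(metadata)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 levels in at least one regressor")
    p = X.shape[1]
    pinv = np.linalg.pinv(X)
    result = _blank_screen(n_channels)
    y = epochs.reshape(n_trials, -1)  # (n, C*T)
    beta = pinv @ y
    resid = y - X @ beta
    rss = (resid**2).sum(axis=0)
    tss = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    df1, df2 = p - 1, n_trials - p
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((tss - rss) / df1) / (rss / df2)
    pvals = stats.f.sf(f, df1, df2).reshape(n_channels, n_time)
    sig = pvals < alpha
    for c in range(n_channels):
        if _longest_run(sig[c]) < run_ms:
            result.unmodulated[c] = True
            result.reason[c] = "unmodulated"
    return result


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


# ---------------------------------------------------------------------------
# Step 8: area-tensor assembly
# ---------------------------------------------------------------------------


def assemble_area_tensor(
    per_probe_epochs: dict[int, np.ndarray | None],
    per_probe_masks: dict[int, np.ndarray] | None = None,
    n_slots: int = len(AREA_LABELS),
) -> list[TrialTensor]:
    """Stack per-probe epoch arrays into channels x time x slot tensors.

    ``per_probe_epochs[slot]``: (n_trials, C_slot, T) or None for an
    absent probe (fully masked slot of zeros).  Probes with fewer
    channels are padded with masked channels up to the maximum C.
    """
    present = {s: e for s, e in per_probe_epochs.items() if e is not None}
    if not present:
        raise ValueError("no probes present")
    n_trials = next(iter(present.values())).shape[0]
    n_time = next(iter(present.values())).shape[2]
    max_c = max(e.shape[1] for e in present.values())
    if len({e.shape[1] for e in present.values()}) > 1:
        logger.info("padding probes to %d channels with masked entries", max_c)
    tensors = []
    for i in range(n_trials):
        values = np.zeros((max_c, n_time, n_slots))
        mask = np.zeros((max_c, n_slots), dtype=bool)
        for s in range(n_slots):
            e = per_probe_epochs.get(s)
            if e is None:
                continue
            c = e.shape[1]
            values[:c, :, s] = e[i]
            if per_probe_masks is not None and s in per_probe_masks:
                mask[:c, s] = per_probe_masks[s]
            else:
                mask[:c, s] = True
        for s in range(n_slots):
            values[~mask[:, s], :, s] = 0.0
        tensors.append(
            TrialTensor(
                values=values,
                channel_mask=mask,
                time_axis=np.arange(-(n_time // 2), n_time - n_time // 2),
            )
        )
    return tensors


# ---------------------------------------------------------------------------
# Full pipeline for one probe
# ---------------------------------------------------------------------------


def preprocess_probe(
    wideband: np.ndarray,
    fs_in: float,
    choice_sample: int,
    metadata: pd.DataFrame,
    known_artifacts: set[int] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, ChannelScreenResult]:
    """Steps 1-7 for a single probe's wideband trials.

    Returns (epochs, channel_mask, screen_result); epochs are
    z-normalized choice-aligned (n_trials, C, 3001) arrays with screened
    channels zeroed.
    """
    screen = detect_bad_channels(wideband, known_artifacts, seed=seed)
    good = ~screen.bad_artifact
    reref = median_rereference(wideband, good)
    mua = extract_mua(reref, fs_in)
    choice_1k = int(round(choice_sample / fs_in * 1000.0))
    epochs, baselines, _ = segment_and_detrend(mua, choice_1k)
    epochs, baselines, valid = znormalize(epochs, baselines)
    mod = screen_task_modulated(epochs, metadata)
    screen.unmodulated = mod.unmodulated
    for c in np.flatnonzero(mod.unmodulated):
        if not screen.reason[c]:
            screen.reason[c] = "unmodulated"
    mask = good & valid & ~mod.unmodulated
    epochs[:, ~mask, :] = 0.0
    return epochs, mask, screen
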