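"""Synthetic multi-area recordings for a multidimensional feature-learning task.

The generators here stand in for primate recordings during a
feature-learning task with "quaddle" objects: parametric visual objects
with four feature dimensions (color, shape, pattern, arms), each having
one neutral value (index 0 by convention) and several non-neutral
values.  A legal object has between one and three non-neutral
dimensions; the number of varying dimensions is constant within a block
of trials, and reward contingencies (token gain/loss levels) change
between blocks.

Three levels of data can be generated:

* trial metadata (``generate_metadata``): block-structured label and
  covariate tables;
* trial-segmented multiunit-activity tensors (``generate_mua``):
  channels x time x area-slot arrays with dimension-specific signals
  planted into configurable carrier channels;
* wideband voltage traces (``generate_wideband``): spike-like
  band-limited transients at a configurable sampling rate, used as the
  input fixture for the preprocessing pipeline.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

AREA_LABELS = ("ACC", "ACC", "PFC", "PFC", "STR", "STR")

# Desk-scale tensor geometry: epoch spans [-1500, +1500] ms around choice
# at 1 kHz; the baseline window is the first 500 ms of the epoch.
T_DEFAULT = 3001
TIME_AXIS_MS = np.arange(-1500, 1501)
BASELINE_SAMPLES = 500
SMOOTH_MS = 200  # Gaussian smoothing window used throughout (FWHM-like width)


def gaussian_window_sigma(window_ms: float) -> float:
    """Standard deviation (in samples at 1 kHz) for a Gaussian window of
    the given nominal width; the window is taken as +/- 3 sigma."""
    return window_ms / 6.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TaskConfig:
    """Task structure: dimensions, feature values, block layout."""

    n_dimensions: int = 4
    n_values_per_dimension: tuple[int, ...] = (3, 3, 3, 3)
    dimensionality_conditions: tuple[int, ...] = (1, 2, 3)
    n_blocks: int = 12
    trials_per_block: tuple[int, int] = (25, 50)
    n_sessions: int = 2
    learning_trials: int = 10  # first k trials of a block are "learning"

    def validate(self) -> None:
        if any(n < 2 for n in self.n_values_per_dimension):
            raise ValueError("every dimension needs >= 2 values (incl. neutral)")
        if len(self.n_values_per_dimension) != self.n_dimensions:
            raise ValueError("n_values_per_dimension length must equal n_dimensions")
        if max(self.dimensionality_conditions) > min(3, self.n_dimensions):
            raise ValueError(
                f"dimensionality {max(self.dimensionality_conditions)} impossible "
                f"with {self.n_dimensions} dimensions (legal objects have 1-3 "
                "non-neutral dimensions)"
            )
        if not all(1 <= d <= 3 for d in self.dimensionality_conditions):
            raise ValueError("dimensionality conditions must lie in {1,2,3}")


@dataclass
class TrialMetadata:
    session_id: str
    block_id: str
    chosen_features: tuple[int, ...]
    outcome: int  # 1 = correct/rewarded
    gain: int  # 1 = high gain
    loss: int  # 1 = high loss
    learned: int  # 1 = learned, 0 = still learning
    previous_reward: int
    dimensionality: int


@dataclass
class TrialTensor:
    """One trial of area-stacked activity: channels x time x area slots."""

    values: np.ndarray  # (C, T, A)
    channel_mask: np.ndarray  # (C, A) boolean, False = removed/empty
    area_labels: tuple[str, ...] = AREA_LABELS
    time_axis: np.ndarray = field(default_factory=lambda: TIME_AXIS_MS.copy())
    baseline_samples: int = BASELINE_SAMPLES


@dataclass
class PlantedSignalSpec:
    """Ground-truth decodable structure injected into carrier channels.

    ``carriers`` maps feature dimension -> list of (slot, channel) pairs.
    With ``encoding='linear'`` the mean of each carrier shifts by
    ``amplitude * value_index`` inside [onset, offset]; with
    ``encoding='xor'`` (binary dimensions only) the carriers are split in
    two halves whose signs agree for value 1 and disagree for value 0,
    with a random per-trial sign, so no single channel's mean carries the
    label.
    """

    carriers: dict[int, list[tuple[int, int]]]
    amplitude: float = 3.0
    onset_ms: int = -500
    offset_ms: int = 500
    profile: str = "box"  # or "ramp"
    encoding: str = "linear"  # or "xor"


# ---------------------------------------------------------------------------
# Metadata generation
# ---------------------------------------------------------------------------


def generate_metadata(config: TaskConfig, seed: int) -> list[TrialMetadata]:
    """Generate block-structured trial metadata.

    Each block has a fixed dimensionality (number of non-neutral
    dimensions of every object), fixed gain/loss levels and a rewarded
    target feature; the chosen object's label is a legal quaddle with
    exactly that many non-neutral values.  Outcome probability rises
    once the learning criterion (first ``learning_trials`` trials) has
    passed.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    trials: list[TrialMetadata] = []
    for s in range(config.n_sessions):
        session = f"session{s:02d}"
        prev_reward = 0
        for b in range(config.n_blocks):
            block = f"{session}_block{b:03d}"
            dim_count = int(rng.choice(config.dimensionality_conditions))
            gain = int(rng.integers(2))
            loss = int(rng.integers(2))
            n_trials = int(rng.integers(config.trials_per_block[0], config.trials_per_block[1] + 1))
            for t in range(n_trials):
                varying = rng.choice(config.n_dimensions, size=dim_count, replace=False)
                label = [0] * config.n_dimensions
                for d in varying:
                    label[d] = int(rng.integers(1, config.n_values_per_dimension[d]))
                learned = int(t >= config.learning_trials)
                p_correct = 0.8 if learned else 0.5
                outcome = int(rng.random() < p_correct)
                trials.append(
                    TrialMetadata(
                        session_id=session,
                        block_id=block,
                        chosen_features=tuple(label),
                        outcome=outcome,
                        gain=gain,
                        loss=loss,
                        learned=learned,
                        previous_reward=prev_reward,
                        dimensionality=dim_count,
                    )
                )
                prev_reward = outcome
    return trials


def metadata_frame(trials: list[TrialMetadata]) -> pd.DataFrame:
    """Tabular view of trial metadata (one row per trial)."""
    rows = []
    for i, tr in enumerate(trials):
        row = asdict(tr)
        feats = row.pop("chosen_features")
        for d, v in enumerate(feats):
            row[f"feature_{d}"] = v
        row["trial_id"] = i
        rows.append(row)
    return pd.DataFrame(rows).set_index("trial_id")


# ---------------------------------------------------------------------------
# MUA-level tensors
# ---------------------------------------------------------------------------


def _signal_profile(spec: PlantedSignalSpec, time_axis: np.ndarray) -> np.ndarray:
    inside = (time_axis >= spec.onset_ms) & (time_axis < spec.offset_ms)
    profile = np.zeros(time_axis.size)
    if spec.profile == "box":
        profile[inside] = 1.0
    elif spec.profile == "ramp":
        span = max(int(inside.sum()), 1)
        profile[inside] = np.linspace(0.0, 1.0, span)
    else:
        raise ValueError(f"unknown profile {spec.profile!r}")
    return profile


def generate_mua(
    metadata: list[TrialMetadata],
    signal: PlantedSignalSpec,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_channels: int = 16,
    n_slots: int = 6,
    n_time: int = T_DEFAULT,
    dtype=np.float64,
) -> list[TrialTensor]:
    """Generate trial tensors with the planted dimension-specific signal.

    The noise floor is Gaussian, temporally smoothed with a 200 ms
    Gaussian kernel (matching the smoothness of preprocessed multiunit
    activity) and rescaled so its pointwise SD equals ``noise_sd``.
    """
    for dim, chans in signal.carriers.items():
        for slot, ch in chans:
            if not (0 <= slot < n_slots and 0 <= ch < n_channels):
                raise ValueError(f"carrier ({slot},{ch}) outside {n_slots}x{n_channels}")
    rng = np.random.default_rng(seed)
    sigma = gaussian_window_sigma(SMOOTH_MS)
    time_axis = np.arange(n_time) - (n_time - 1) // 2
    profile = _signal_profile(signal, time_axis)
    tensors: list[TrialTensor] = []
    mask = np.ones((n_channels, n_slots), dtype=bool)
    for tr in metadata:
        noise = rng.standard_normal((n_channels, n_time, n_slots))
        noise = gaussian_filter1d(noise, sigma, axis=1)
        # smoothing shrinks the SD; restore it so the floor is noise_sd z-units
        noise *= noise_sd / max(noise.std(), 1e-12)
        values = noise
        for dim, chans in signal.carriers.items():
            v = tr.chosen_features[dim]
            if signal.encoding == "linear":
                bump = signal.amplitude * v * profile
                for slot, ch in chans:
                    values[ch, :, slot] += bump
            elif signal.encoding == "xor":
                sign = 1.0 if rng.random() < 0.5 else -1.0
                half = len(chans) // 2
                agree = 1.0 if v != 0 else -1.0
                for k, (slot, ch) in enumerate(chans):
                    s = sign if k < half else sign * agree
                    values[ch, :, slot] += signal.amplitude * s * profile
            else:
                raise ValueError(f"unknown encoding {signal.encoding!r}")
        tensors.append(
            TrialTensor(
                values=values.astype(dtype, copy=False),
                channel_mask=mask.copy(),
                time_axis=time_axis.copy(),
            )
        )
    return tensors


# ---------------------------------------------------------------------------
# Wideband-level traces
# ---------------------------------------------------------------------------


@dataclass
class WidebandTrials:
    """Per-trial wideband voltage traces for one probe."""

    values: np.ndarray  # (n_trials, C, n_samples)
    fs_hz: float
    choice_sample: int  # sample index of the choice within each trial trace


def generate_wideband(
    metadata: list[TrialMetadata],
    signal: PlantedSignalSpec | None = None,
    sampling_rate_hz: float = 12_000.0,
    seed: int = 0,
    n_channels: int = 16,
    duration_ms: float = 4000.0,
    choice_ms: float = 2000.0,
    base_rate_hz: float = 40.0,
    rate_modulation: float = 1.0,
    common_mode_sd: float = 0.0,
    artifact_channels: tuple[int, ...] = (),
) -> WidebandTrials:
    """Spike-like wideband traces whose transient rate co-varies with the
    planted features (single probe).

    Transients are biphasic ~1.5 kHz wavelets at Poisson times; the rate
    on carrier channels is multiplied by ``1 + rate_modulation * value``
    inside the planted window.  ``common_mode_sd`` adds noise shared by
    all channels of the probe; ``artifact_channels`` get 10x-variance
    noise.
    """
    if sampling_rate_hz < 10_000:
        raise ValueError("sampling rate must be >= 10 kHz for the 0.75-5 kHz band")
    rng = np.random.default_rng(seed)
    fs = float(sampling_rate_hz)
    n_samp = int(round(duration_ms / 1000.0 * fs))
    # biphasic spike wavelet centred in the 0.75-5 kHz band
    t_w = np.arange(-int(0.0015 * fs), int(0.0015 * fs) + 1) / fs
    wavelet = np.sin(2 * np.pi * 1500 * t_w) * np.exp(-((t_w / 4e-4) ** 2))
    carrier_of_channel: dict[int, int] = {}
    if signal is not None:
        for dim, chans in signal.carriers.items():
            for _slot, ch in chans:
                carrier_of_channel[ch] = dim
    choice_idx = int(round(choice_ms / 1000.0 * fs))
    out = np.zeros((len(metadata), n_channels, n_samp))
    time_ms = np.arange(n_samp) / fs * 1000.0 - choice_ms
    window = np.ones(n_samp, dtype=bool)
    if signal is not None:
        window = (time_ms >= signal.onset_ms) & (time_ms < signal.offset_ms)
    for i, tr in enumerate(metadata):
        traces = rng.standard_normal((n_channels, n_samp)) * 0.05
        if common_mode_sd > 0:
            traces += common_mode_sd * rng.standard_normal(n_samp)[None, :]
        for ch in range(n_channels):
            rate = np.full(n_samp, base_rate_hz / fs)
            dim = carrier_of_channel.get(ch)
            if dim is not None:
                v = tr.chosen_features[dim]
                rate[window] *= 1.0 + rate_modulation * v
            spikes = rng.random(n_samp) < rate
            amp = 1.0 + 0.2 * rng.standard_normal(int(spikes.sum()))
            train = np.zeros(n_samp)
            train[np.flatnonzero(spikes)] = amp
            traces[ch] += np.convolve(train, wavelet, mode="same")
        for ch in artifact_channels:
            traces[ch] += rng.standard_normal(n_samp) * 0.5  # 10x base variance
        out[i] = traces
    return WidebandTrials(values=out, fs_hz=fs, choice_sample=choice_idx)


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------


def write_dataset(
    path,
    tensors: list[TrialTensor],
    metadata: list[TrialMetadata],
    config: TaskConfig | None = None,
    signal: PlantedSignalSpec | None = None,
) -> None:
    """Write tensors to HDF5 with a companion metadata CSV and JSON sidecar."""
    path = str(path)
    with h5py.File(path, "w") as f:
        f.attrs["n_trials"] = len(tensors)
        f.attrs["area_labels"] = list(AREA_LABELS)
        grp = f.create_group("trials")
        for i, tensor in enumerate(tensors):
            g = grp.create_group(str(i))
            g.create_dataset("values", data=tensor.values)
            g.create_dataset("mask", data=tensor.channel_mask)
            g.attrs["baseline_samples"] = tensor.baseline_samples
            g.attrs["time_start_ms"] = int(tensor.time_axis[0])
    metadata_frame(metadata).to_csv(path + ".metadata.csv")
    sidecar = {}
    if config is not None:
        sidecar["task_config"] = asdict(config)
    if signal is not None:
        d = asdict(signal)
        d["carriers"] = {str(k): v for k, v in d["carriers"].items()}
        sidecar["planted_signal"] = d
    if sidecar:
        with open(path + ".config.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, default=list)


def read_dataset(path) -> tuple[list[TrialTensor], pd.DataFrame]:
    """Read tensors and the metadata table written by :func:`write_dataset`."""
    path = str(path)
    tensors = []
    with h5py.File(path, "r") as f:
        n = int(f.attrs["n_trials"])
        for i in range(n):
            g = f["trials"][str(i)]
            values = g["values"][()]
            t0 = int(g.attrs["time_start_ms"])
            tensors.append(
                TrialTensor(
                    values=values,
                    channel_mask=g["mask"][()].astype(bool),
                    time_axis=np.arange(t0, t0 + values.shape[1]),
                    baseline_samples=int(g.attrs["baseline_samples"]),
                )
            )
    meta = pd.read_csv(path + ".metadata.csv", index_col="trial_id")
    return tensors, meta


def labels_array(meta: pd.DataFrame, n_dimensions: int = 4) -> np.ndarray:
    """(n_trials, M) integer label matrix from a metadata table."""
    cols = [f"feature_{d}" for d in range(n_dimensions)]
    return meta[cols].to_numpy(dtype=int)


def default_carriers(
    n_dimensions: int = 4, per_dim: int = 8, n_channels: int = 16
) -> dict[int, list[tuple[int, int]]]:
    """Assign ``per_dim`` carrier channels per dimension.

    Dimension d's carriers live on slot ``d % 6`` (so each of the first
    four area slots carries one dimension), channels 0..per_dim-1.
    """
    return {
        d: [(d % len(AREA_LABELS), ch) for ch in range(min(per_dim, n_channels))]
        for d in range(n_dimensions)
    }
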