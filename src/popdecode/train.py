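"""Training: dataset normalization, augmentation, the three-component loss
with adaptive weighting, the optimization schedule, and model selection.

The total loss is a weighted sum of three components,

    L = lambda_r * L_r + lambda_c * L_c + lambda_KL * L_KL,

where L_r is the masked mean-squared reconstruction error, L_c the
class-weighted cross-entropy summed over feature dimensions, and L_KL
the closed-form KL divergence of the latent Gaussian from a standard
normal,

    L_KL = 1/2 sum_i (mu_i^2 + sigma_i^2 - log sigma_i^2 - 1).

At the start of every epoch the effective weights are rebalanced from
the first-iteration component losses so that the weighted components
hold the ratio of their weight factors: lambda_i = omega_i / L_i(prior).
(The alternative product rule lambda_i = omega_i * L_i(prior) is
available behind ``printed_lambda_rule`` but does not maintain the
ratio.)

The learning rate ramps linearly over the first 5 epochs and decays by
90% every 30 epochs.  Gradients are accumulated over sub-batches,
L2-clipped per network component (encoder / decoder / classifier) at a
threshold of 100, and applied with SGD or ADAM plus L2 regularization.
The best checkpoint is the one with the highest peak validation scaled
balanced accuracy over windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import interpret, metrics
from .autodiff import Tensor
from .model import ArchitectureConfig, Network, NetworkOutput, window_trials
from .synth import gaussian_window_sigma

logger = logging.getLogger("popdecode.train")

RAMP_EPOCHS = 5
DECAY_EVERY = 30
DECAY_FACTOR = 0.1

# augmentation noise SDs (z-ish units of the normalized data)
OFFSET_SD = 0.3
WHITE_SD = 0.15
WALK_STEP_SD = 0.007
NOISE_SMOOTH_MS = 50


# ---------------------------------------------------------------------------
# Dataset normalization
# ---------------------------------------------------------------------------


def normalize_dataset(values: np.ndarray, channel_mask: np.ndarray) -> np.ndarray:
    """Four-step normalization of the stacked trial tensor (n, C, T, A).

    (1) z-score each channel over all trials and time points; (2) min-max
    scale the whole array to [-1, 1]; (3) recenter so the global mean is
    0; (4) rescale so the global SD is 0.25.  Masked channels are set to
    0 and excluded from every statistic.
    """
    values = np.array(values, copy=True)  # keeps the caller's float precision
    if not np.issubdtype(values.dtype, np.floating):
        values = values.astype(np.float64)
    mask = np.asarray(channel_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no unmasked channels")
    # step 1: per-channel z-score (statistics in float64, updates in place)
    mu = values.mean(axis=(0, 2), dtype=np.float64)  # (C, A)
    sd = values.std(axis=(0, 2), dtype=np.float64)
    if np.all(sd[mask] < 1e-15):
        raise ValueError("zero variance on every unmasked channel")
    sd_safe = np.where(sd > 1e-15, sd, 1.0)
    values -= mu[None, :, None, :].astype(values.dtype)
    values /= sd_safe[None, :, None, :].astype(values.dtype)
    vt = values.transpose(0, 2, 1, 3)  # (n, T, C, A) view; (C, A) mask applies
    vt[:, :, ~mask] = 0.0
    # step 2: global min-max to [-1, 1]
    unmasked = vt[:, :, mask]
    lo, hi = float(unmasked.min()), float(unmasked.max())
    if hi - lo < 1e-15:
        raise ValueError("zero global variance")
    vt[:, :, mask] = 2.0 * (unmasked - lo) / (hi - lo) - 1.0
    # steps 3-4: recenter to mean 0 and rescale to SD 0.25
    unmasked = vt[:, :, mask]
    center = unmasked.mean(dtype=np.float64)
    scale = unmasked.std(dtype=np.float64)
    vt[:, :, mask] = (unmasked - center) / scale * 0.25
    return values


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def augment_noise(
    batch: np.ndarray,
    seed: int | np.random.Generator,
    time_bin_ms: int = 1,
) -> np.ndarray:
    """Add per-channel offset + white noise + random walk, then smooth.

    ``batch``: (B, S, C, Wb, A) windowed trials; the noise runs along the
    concatenated window time of each trial (length S*Wb per channel) so
    the random walk is continuous across windows.  The summed noise is
    smoothed with a 50 ms Gaussian window before being added, matching
    the frequency content of the data.  Fresh noise every call.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b, s, c, wb, a = batch.shape
    t = s * wb
    # (B, C, A, t) noise workspace
    offset = rng.normal(0.0, OFFSET_SD, size=(b, c, a, 1))
    white = rng.normal(0.0, WHITE_SD, size=(b, c, a, t))
    walk = np.cumsum(rng.normal(0.0, WALK_STEP_SD, size=(b, c, a, t)), axis=-1)
    noise = offset + white + walk
    sigma = gaussian_window_sigma(NOISE_SMOOTH_MS) / max(time_bin_ms, 1)
    if sigma >= 0.3:
        noise = gaussian_filter1d(noise, sigma, axis=-1)
    noise = noise.reshape(b, c, a, s, wb).transpose(0, 3, 1, 4, 2)
    return batch + noise


# ---------------------------------------------------------------------------
# Class weights and loss
# ---------------------------------------------------------------------------


def class_weights(labels: np.ndarray, dim_sizes: list[int]) -> list[np.ndarray]:
    """Inverse-frequency class weights per dimension, normalized to mean 1.

    Rarer classes get larger weights, countering the dominance of the
    neutral feature.  Classes absent from the training set get the
    maximum observed weight.
    """
    out = []
    n = labels.shape[0]
    for j, nj in enumerate(dim_sizes):
        counts = np.bincount(labels[:, j], minlength=nj).astype(float)
        w = np.where(counts > 0, n / np.maximum(counts, 1), 0.0)
        w[counts == 0] = w.max() if w.max() > 0 else 1.0
        out.append(w / w.mean())
    return out


@dataclass
class LossWeights:
    """Weight factors omega and per-epoch effective weights lambda."""

    omega: tuple[float, float, float] = (1.0, 1.0, 0.1)  # (r, c, KL)
    lambdas: np.ndarray = field(default_factory=lambda: np.ones(3))
    printed_rule: bool = False


def update_lambdas(weights: LossWeights, prior_losses: tuple[float, float, float]) -> LossWeights:
    """Reset the effective weights from first-iteration component losses.

    Default rule lambda_i = omega_i / L_i(prior) keeps the weighted
    component ratio at the omega ratio; zero priors carry the previous
    lambda forward (logged).
    """
    lams = weights.lambdas.copy()
    for i, (om, prior) in enumerate(zip(weights.omega, prior_losses)):
        if prior <= 0:
            logger.info("component %d prior loss is 0; carrying lambda over", i)
            continue
        lams[i] = om * prior if weights.printed_rule else om / prior
    weights.lambdas = lams
    return weights


def kl_loss(mu: Tensor, logvar: Tensor) -> Tensor:
    """Closed-form KL(N(mu, sigma^2) || N(0, I)), mean over leading axes."""
    var = logvar.exp()
    per_item = (mu * mu + var - logvar - 1.0).sum(axis=-1) * 0.5
    return per_item.mean()


def compute_loss(
    output: NetworkOutput,
    target: np.ndarray,
    labels: np.ndarray,
    weights: LossWeights,
    channel_mask: np.ndarray,
    cls_weights: list[np.ndarray],
) -> tuple[Tensor, dict[str, float]]:
    """Weighted sum of reconstruction, classification and KL losses.

    ``target``: (B, S, C, Wb, A); ``labels``: (B, M).  Masked channels
    contribute exactly zero to the reconstruction term.
    """
    b, s, c, wb, a = target.shape
    mask = np.asarray(channel_mask, bool)
    n_unmasked = int(mask.sum())
    mask_arr = Tensor(mask.astype(float)[None, None, :, None, :])
    diff = output.reconstruction - Tensor(target)
    l_r = (diff * diff * mask_arr).sum() * (1.0 / (b * s * wb * max(n_unmasked, 1)))
    # classification: Eq.-(10)-style class-weighted binary cross-entropy sum
    l_c = None
    for j, logp in enumerate(output.class_logprobs):
        nj = logp.shape[-1]
        onehot = np.eye(nj)[labels[:, j]]  # (B, Nj)
        y = Tensor(np.broadcast_to(onehot[:, None, :], (b, s, nj)).copy())
        w = Tensor(cls_weights[j][None, None, :])
        p = output.class_probs[j]
        term = -(w * (y * logp + (1.0 - y) * ((1.0 - p) + 1e-12).log())).sum(axis=-1)
        contrib = term.mean()
        l_c = contrib if l_c is None else l_c + contrib
    l_kl = kl_loss(output.mu, output.logvar)
    lam = weights.lambdas
    total = l_r * lam[0] + l_c * lam[1] + l_kl * lam[2]
    parts = {
        "reconstruction": float(l_r.data),
        "classification": float(l_c.data),
        "kl": float(l_kl.data),
        "total": float(total.data),
    }
    if not np.isfinite(parts["total"]):
        raise FloatingPointError(f"non-finite loss: {parts}")
    return total, parts


# ---------------------------------------------------------------------------
# Schedule, optimizers, gradient handling
# ---------------------------------------------------------------------------


def lr_schedule(epoch: int, initial_lr: float) -> float:
    """Linear ramp from 0 over epochs 1-5, then x0.1 at every 30-epoch
    boundary (epoch 31 -> 0.1 lr, epoch 61 -> 0.01 lr)."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    if epoch <= RAMP_EPOCHS:
        return initial_lr * epoch / RAMP_EPOCHS
    return initial_lr * DECAY_FACTOR ** ((epoch - 1) // DECAY_EVERY)


def clip_gradients(grads: dict[str, np.ndarray], threshold: float, components=("enc", "dec", "cls")) -> dict[str, np.ndarray]:
    """Scale each component's gradient to L2 norm <= threshold."""
    out = dict(grads)
    for comp in components:
        keys = [k for k in grads if k.startswith(comp + "/")]
        norm = np.sqrt(sum(float((grads[k] ** 2).sum()) for k in keys))
        if norm > threshold:
            scale = threshold / norm
            for k in keys:
                out[k] = grads[k] * scale
    return out


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    initial_lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    accumulation_steps: int = 1
    grad_clip: float = 100.0
    l2: float = 1e-5
    omega: tuple[float, float, float] = (1.0, 1.0, 0.1)
    printed_lambda_rule: bool = False
    augment: bool = True
    seed: int = 0


class Optimizer:
    """SGD or ADAM over the parameter dict, with L2 regularization."""

    def __init__(self, network: Network, config: TrainConfig):
        self.network = network
        self.kind = config.optimizer
        self.l2 = config.l2
        self.t = 0
        if self.kind == "adam":
            self.m = {k: np.zeros_like(p.data) for k, p in network.params.items()}
            self.v = {k: np.zeros_like(p.data) for k, p in network.params.items()}
        elif self.kind != "sgd":
            raise ValueError(f"unknown optimizer {self.kind!r}")

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, p in self.network.params.items():
            if k not in grads:
                continue
            g = grads[k] + self.l2 * p.data
            if self.kind == "sgd":
                p.data = p.data - lr * g
            else:
                self.m[k] = b1 * self.m[k] + (1 - b1) * g
                self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
                mh = self.m[k] / (1 - b1**self.t)
                vh = self.v[k] / (1 - b2**self.t)
                p.data = p.data - lr * mh / (np.sqrt(vh) + eps)


# ---------------------------------------------------------------------------
# Epoch loop and fitting
# ---------------------------------------------------------------------------


@dataclass
class TrainState:
    epoch: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    best_score: float = -np.inf
    best_epoch: int = -1
    best_weights: dict | None = None
    history: list[dict] = field(default_factory=list)


def _batch_gradients(
    network: Network,
    windows: np.ndarray,
    labels: np.ndarray,
    weights: LossWeights,
    channel_mask: np.ndarray,
    cls_weights: list[np.ndarray],
    rng: np.random.Generator,
    accumulation_steps: int,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Gradients of the batch loss, accumulated over sub-batches.

    Sub-batch gradients are weighted by sub-batch size so their sum
    equals the full-batch gradient of the mean-based loss.
    """
    network.zero_grad()
    n = windows.shape[0]
    splits = np.array_split(np.arange(n), min(accumulation_steps, n))
    parts_acc = {"reconstruction": 0.0, "classification": 0.0, "kl": 0.0, "total": 0.0}
    for idx in splits:
        out = network.forward(windows[idx], rng=rng, training=True)
        loss, parts = compute_loss(
            out, windows[idx], labels[idx], weights, channel_mask, cls_weights
        )
        frac = len(idx) / n
        (loss * frac).backward()
        for k in parts_acc:
            parts_acc[k] += parts[k] * frac
    grads = {k: p.grad for k, p in network.params.items() if p.grad is not None}
    return grads, parts_acc


def train_epoch(
    network: Network,
    optimizer: Optimizer,
    windows: np.ndarray,
    labels: np.ndarray,
    channel_mask: np.ndarray,
    cls_weights: list[np.ndarray],
    state: TrainState,
    config: TrainConfig,
) -> TrainState:
    """One pass over the training set with fresh random mini-batches."""
    state.epoch += 1
    rng = np.random.default_rng(config.seed + 7919 * state.epoch)
    lr = lr_schedule(state.epoch, config.initial_lr)
    order = rng.permutation(windows.shape[0])
    first = True
    for lo in range(0, len(order), config.batch_size):
        idx = order[lo : lo + config.batch_size]
        batch = windows[idx]
        if config.augment:
            batch = augment_noise(batch, rng, time_bin_ms=network.config.time_bin_ms)
        try:
            grads, parts = _batch_gradients(
                network, batch, labels[idx], state.weights, channel_mask,
                cls_weights, rng, config.accumulation_steps,
            )
        except FloatingPointError as err:
            logger.warning("skipping step with non-finite loss: %s", err)
            continue
        if first:
            update_lambdas(
                state.weights,
                (parts["reconstruction"], parts["classification"], parts["kl"]),
            )
            first = False
        if any(not np.isfinite(g).all() for g in grads.values()):
            logger.warning("skipping step with non-finite gradient")
            continue
        grads = clip_gradients(grads, config.grad_clip)
        optimizer.step(grads, lr)
    return state


def select_best(state: TrainState) -> dict:
    """Weights of the epoch with the highest peak validation accuracy
    (ties resolved toward the earlier epoch)."""
    if state.best_weights is None:
        raise ValueError("no evaluated epoch")
    return state.best_weights


def validation_peak(
    network: Network,
    windows: np.ndarray,
    labels: np.ndarray,
    dim_sizes: list[int],
    repair_legality: bool | None = None,
) -> tuple[float, np.ndarray]:
    """Peak (over windows) scaled balanced accuracy on one evaluation set.

    Legality repair applies to the four-dimension quaddle label space;
    for other label spaces the plain per-dimension argmax is used.
    """
    if repair_legality is None:
        repair_legality = len(dim_sizes) == 4
    probs = network.predict_proba(windows)
    if repair_legality:
        preds = interpret.decode_batch(probs)  # (n, S, M)
    else:
        preds = np.stack([p.argmax(axis=-1) for p in probs], axis=-1)
    chance = metrics.chance_ba(dim_sizes)
    scores = []
    for s in range(preds.shape[1]):
        conf = metrics.confusion_from_predictions(labels, preds[:, s, :], dim_sizes)
        scores.append(
            metrics.scaled_balanced_accuracy(
                metrics.multilabel_balanced_accuracy(conf), chance
            )
        )
    scores = np.array(scores)
    return float(scores.max()), scores


def fit(
    train_windows: np.ndarray,
    train_labels: np.ndarray,
    val_windows: np.ndarray,
    val_labels: np.ndarray,
    dim_sizes: list[int],
    channel_mask: np.ndarray,
    arch: ArchitectureConfig,
    config: TrainConfig,
) -> tuple[Network, TrainState]:
    """Train a network and keep the checkpoint with the best validation peak."""
    network = Network(
        arch,
        tuple(train_windows.shape[2:]),
        dim_sizes,
        seed=config.seed,
        channel_mask=channel_mask,
    )
    optimizer = Optimizer(network, config)
    cw = class_weights(train_labels, dim_sizes)
    state = TrainState(weights=LossWeights(omega=config.omega, printed_rule=config.printed_lambda_rule))
    for _ in range(config.epochs):
        train_epoch(
            network, optimizer, train_windows, train_labels, channel_mask, cw, state, config
        )
        peak, curve = validation_peak(network, val_windows, val_labels, dim_sizes)
        state.history.append(
            {
                "epoch": state.epoch,
                "lr": lr_schedule(state.epoch, config.initial_lr),
                "lambdas": state.weights.lambdas.tolist(),
                "val_peak": peak,
            }
        )
        if peak > state.best_score:  # strict: ties keep the earlier epoch
            state.best_score = peak
            state.best_epoch = state.epoch
            state.best_weights = network.get_weights()
    network.set_weights(select_best(state))
    return network, state


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, network: Network, extra: dict | None = None) -> None:
    """Serialize weights plus the architecture config and a config hash."""
    import hashlib
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg = asdict(network.config)
    meta = {
        "architecture": cfg,
        "dim_sizes": network.dim_sizes,
        "input_shape": list(network.input_shape),
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:12],
        **(extra or {}),
    }
    np.savez(path, __meta__=json.dumps(meta), __mask__=network.channel_mask,
             **network.get_weights())


def load_checkpoint(path) -> Network:
    """Rebuild a network from a checkpoint written by save_checkpoint."""
    import json

    from .model import ArchitectureConfig

    with np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
        meta = json.loads(str(data["__meta__"]))
        mask = data["__mask__"]
        weights = {k: data[k] for k in data.files if not k.startswith("__")}
    net = Network(
        ArchitectureConfig(**meta["architecture"]),
        tuple(meta["input_shape"]),
        meta["dim_sizes"],
        channel_mask=mask,
    )
    net.set_weights(weights)
    return net
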