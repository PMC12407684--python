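"""Encoder-decoder-classifier network over windowed trial tensors.

A trial tensor X (channels x time x area slots) is cut into S sliding
windows X[s] of width W.  In the video analogy, channels and
within-window time are the spatial axes, the area slot is the image
channel, and the window index s is frame time.  The network has three
parts sharing a variational bottleneck:

* encoder: a stack of blocks with halving unit counts whose final layer
  has 2L units holding the latent mean and log-variance;
* decoder: a sampling layer (reparameterized draw from N(mu, sigma^2))
  followed by a mirrored growing stack reconstructing the window;
* classifiers: one head per feature dimension, reading the encoder
  output (the 2L bottleneck vector) and emitting a probability vector
  over that dimension's feature values per window.

Six block families are available: feedforward (ReLU), GRU and LSTM
(recurrent over the window sequence), convolutional (leaky ReLU, 2x2
max-pool), residual (convolutional plus a strided-convolution skip
path) and multi-filter (three parallel convolutional blocks with kernel
sizes 20/30/40% of the window image, concatenated).  Every block
carries dropout and a normalization layer; layer normalization is used
because batch statistics are unstable at small batch sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

RECURRENT = ("gru", "lstm")
CONVOLUTIONAL = ("conv", "resnet", "multifilter")
FAMILIES = ("feedforward",) + RECURRENT + CONVOLUTIONAL


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ArchitectureConfig:
    """Hyper-parameters of the network (the sweep axes).

    ``first_layer_size`` starts the halving encoder stack; the stack has
    ``n_layers`` layers of which the last always has 2 x ``latent_size``
    units for the mean and variance components.  ``time_bin_ms``
    mean-bins each window along time before the network; 1 disables
    binning.
    """

    block_family: str = "gru"
    n_layers: int = 3
    first_layer_size: int = 64
    bottleneck_depth: int = 1
    latent_size: int = 500
    window_width_ms: int = 500
    stride_ms: int = 250
    classifier_family: str = "feedforward"
    classifier_hidden: int = 32
    dropout_rate: float = 0.2
    layer_norm: bool = True
    time_bin_ms: int = 25
    conv_filters: int = 8

    def validate(self) -> None:
        if self.block_family not in FAMILIES:
            raise ValueError(f"unknown block family {self.block_family!r}")
        if self.classifier_family not in ("feedforward", "lstm"):
            raise ValueError(f"unknown classifier family {self.classifier_family!r}")
        if self.n_layers < 1 or self.latent_size < 1:
            raise ValueError("n_layers and latent_size must be positive")
        if self.window_width_ms % self.time_bin_ms:
            raise ValueError("window width must be a multiple of the time bin")


@dataclass
class WindowedInput:
    """Sliding windows X[s] with their time mapping."""

    windows: np.ndarray  # (n_trials, S, C, Wb, A)
    window_times_ms: np.ndarray  # (S,) center of each window
    window_width_ms: int
    stride_ms: int

    @property
    def n_windows(self) -> int:
        return self.windows.shape[1]


def window_trials(
    values: np.ndarray,
    window_width_ms: int,
    stride_ms: int,
    time_bin_ms: int = 1,
    time_axis: np.ndarray | None = None,
) -> WindowedInput:
    """Cut (n, C, T, A) trial arrays into S windows of width W.

    S = floor((T - W) / stride) + 1.  With ``time_bin_ms`` > 1 each
    window's time axis is mean-binned by that factor, giving windows of
    shape (C, W/bin, A).
    """
    n, c, t, a = values.shape
    w, stride = window_width_ms, stride_ms
    if w > t:
        raise ValueError(f"window width {w} exceeds trial length {t}")
    s = (t - w) // stride + 1
    if time_axis is None:
        time_axis = np.arange(t) - (t - 1) // 2
    starts = np.arange(s) * stride
    wb = w // time_bin_ms
    out = np.empty((n, s, c, wb, a))
    for i, st in enumerate(starts):
        win = values[:, :, st : st + w, :]
        if time_bin_ms > 1:
            win = win.reshape(n, c, wb, time_bin_ms, a).mean(axis=3)
        out[:, i] = win
    centers = np.array([time_axis[st] + w // 2 for st in starts], dtype=float)
    return WindowedInput(out, centers, w, stride)


# ---------------------------------------------------------------------------
# Parameter initialisation helpers
# ---------------------------------------------------------------------------


class _ParamStore:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.params: dict[str, Tensor] = {}

    def dense(self, name: str, n_in: int, n_out: int):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.params[f"{name}/W"] = Tensor(
            self.rng.uniform(-limit, limit, (n_in, n_out)), requires_grad=True
        )
        self.params[f"{name}/b"] = Tensor(np.zeros(n_out), requires_grad=True)

    def norm(self, name: str, n: int):
        self.params[f"{name}/gain"] = Tensor(np.ones(n), requires_grad=True)
        self.params[f"{name}/bias"] = Tensor(np.zeros(n), requires_grad=True)

    def gates(self, name: str, n_in: int, n_hidden: int, n_gates: int):
        limit = np.sqrt(6.0 / (n_in + n_hidden))
        self.params[f"{name}/Wx"] = Tensor(
            self.rng.uniform(-limit, limit, (n_in, n_gates * n_hidden)), requires_grad=True
        )
        self.params[f"{name}/Wh"] = Tensor(
            self.rng.uniform(-limit, limit, (n_hidden, n_gates * n_hidden)),
            requires_grad=True,
        )
        self.params[f"{name}/b"] = Tensor(np.zeros(n_gates * n_hidden), requires_grad=True)

    def conv(self, name: str, c_in: int, c_out: int, kh: int, kw: int, transpose=False):
        fan = c_in * kh * kw + c_out * kh * kw
        limit = np.sqrt(6.0 / fan)
        shape = (c_in, c_out, kh, kw) if transpose else (c_out, c_in, kh, kw)
        self.params[f"{name}/W"] = Tensor(
            self.rng.uniform(-limit, limit, shape), requires_grad=True
        )
        self.params[f"{name}/b"] = Tensor(np.zeros(c_out), requires_grad=True)


@dataclass
class NetworkOutput:
    reconstruction: Tensor  # (B, S, C, Wb, A)
    class_probs: list[Tensor]  # per dimension: (B, S, Nj)
    class_logprobs: list[Tensor]
    mu: Tensor  # (B, S, L)
    logvar: Tensor
    z: Tensor


def reparameterized_sample(mu: Tensor, logvar: Tensor, rng: np.random.Generator) -> Tensor:
    """Z = mu + sigma * eps with eps ~ N(0, I); gradients flow to both
    the mean and the (log-)variance."""
    eps = Tensor(rng.standard_normal(mu.data.shape))
    return mu + (logvar * 0.5).exp() * eps


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------


class Network:
    """Gated-recurrent (or alternative-family) variational autoencoder with
    per-dimension classifier heads."""

    def __init__(
        self,
        config: ArchitectureConfig,
        input_shape: tuple[int, int, int],
        dim_sizes: list[int],
        seed: int = 0,
        channel_mask: np.ndarray | None = None,
    ):
        config.validate()
        self.config = config
        self.input_shape = tuple(input_shape)  # (C, Wb, A)
        self.dim_sizes = list(dim_sizes)
        c_, _, a_ = self.input_shape
        self.channel_mask = (
            np.ones((c_, a_), bool) if channel_mask is None else np.asarray(channel_mask, bool)
        )
        c, wb, a = self.input_shape
        self.flat_size = c * wb * a
        store = _ParamStore(np.random.default_rng(seed))
        L = config.latent_size
        fam = config.block_family

        # encoder hidden sizes: halving stack, final layer replaced by 2L
        hidden = [max(config.first_layer_size // (2**i), 2) for i in range(config.n_layers - 1)]
        self.encoder_hidden = hidden
        self.decoder_sizes = list(reversed(hidden)) or [max(2, config.first_layer_size // 2)]

        if fam in CONVOLUTIONAL:
            self._build_conv(store, hidden)
        else:
            prev = self.flat_size
            for i, h in enumerate(hidden):
                if fam == "feedforward":
                    store.dense(f"enc/l{i}", prev, h)
                else:
                    store.gates(f"enc/l{i}", prev, h, 3 if fam == "gru" else 4)
                store.norm(f"enc/n{i}", h)
                prev = h
            store.dense("enc/final", prev, 2 * L)
        for d in range(config.bottleneck_depth):
            store.dense(f"enc/bottleneck{d}", 2 * L, 2 * L)

        # decoder: sampling layer (L) then growing mirror
        if fam in CONVOLUTIONAL:
            self._build_conv_decoder(store)
        else:
            sizes = self.decoder_sizes
            store.dense("dec/in", L, sizes[0])
            prev = sizes[0]
            for i, h in enumerate(sizes):
                nxt = sizes[i + 1] if i + 1 < len(sizes) else None
                if fam == "feedforward":
                    store.dense(f"dec/l{i}", prev, h)
                else:
                    store.gates(f"dec/l{i}", prev, h, 3 if fam == "gru" else 4)
                store.norm(f"dec/n{i}", h)
                prev = h
            store.dense("dec/out", prev, self.flat_size)

        # classifier heads: input = encoder output (2L)
        for j, nj in enumerate(self.dim_sizes):
            if config.classifier_family == "lstm":
                store.gates(f"cls/h{j}", 2 * L, config.classifier_hidden, 4)
                store.norm(f"cls/n{j}", config.classifier_hidden)
            else:
                store.dense(f"cls/h{j}", 2 * L, config.classifier_hidden)
                store.norm(f"cls/n{j}", config.classifier_hidden)
            store.dense(f"cls/out{j}", config.classifier_hidden, nj)
        self.params = store.params

    # -- conv geometry -------------------------------------------------------

    def _conv_sizes(self):
        c, wb, a = self.input_shape
        sizes = [(c, wb)]
        for _ in range(max(self.config.n_layers - 1, 1)):
            h, w = sizes[-1]
            sizes.append((max(h // 2, 1), max(w // 2, 1)))
        return sizes

    def _kernel(self, frac: float):
        c, wb, _ = self.input_shape
        return max(1, round(frac * c)), max(1, round(frac * wb))

    def _build_conv(self, store: _ParamStore, hidden):
        cfg = self.config
        _, _, a = self.input_shape
        f = cfg.conv_filters
        n_blocks = max(cfg.n_layers - 1, 1)
        fracs = (0.2, 0.3, 0.4) if cfg.block_family == "multifilter" else (0.3,)
        c_in = a
        for i in range(n_blocks):
            for frac in fracs:
                kh, kw = self._kernel(frac)
                store.conv(f"enc/b{i}/conv{frac}", c_in, f, kh, kw)
            c_out = f * len(fracs)
            store.norm(f"enc/n{i}", c_out)
            if cfg.block_family == "resnet":
                store.conv(f"enc/b{i}/skip", c_in, c_out, 2, 2)
            c_in = c_out
        hf, wf = self._conv_sizes()[n_blocks]
        store.dense("enc/final", c_in * hf * wf, 2 * cfg.latent_size)
        self._conv_channels = c_in

    def _build_conv_decoder(self, store: _ParamStore):
        cfg = self.config
        _, _, a = self.input_shape
        f = cfg.conv_filters
        n_blocks = max(cfg.n_layers - 1, 1)
        fracs = (0.2, 0.3, 0.4) if cfg.block_family == "multifilter" else (0.3,)
        sizes = self._conv_sizes()
        hf, wf = sizes[n_blocks]
        store.dense("dec/in", cfg.latent_size, self._conv_channels * hf * wf)
        c_in = self._conv_channels
        for i in range(n_blocks):
            last = i == n_blocks - 1
            c_out = a if last else f * len(fracs)
            per_path = a if last and len(fracs) == 1 else (
                max(1, c_out // len(fracs)) if not last else a
            )
            for frac in fracs:
                kh, kw = self._kernel(frac)
                store.conv(f"dec/b{i}/tconv{frac}", c_in, c_in, kh, kw, transpose=True)
                store.conv(f"dec/b{i}/conv{frac}", c_in, per_path, kh, kw)
            eff_out = per_path * len(fracs)
            store.norm(f"dec/n{i}", eff_out)
            if cfg.block_family == "resnet":
                store.conv(f"dec/b{i}/skip", c_in, eff_out, 2, 2, transpose=True)
            c_in = eff_out
        # final 1x1 conv maps concatenated paths to the A area channels
        store.conv("dec/out", c_in, a, 1, 1)

    # -- building blocks -----------------------------------------------------

    def _dense(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}/W"] + self.params[f"{name}/b"]

    def _norm(self, name: str, x: Tensor) -> Tensor:
        if not self.config.layer_norm:
            return x
        return ad.layer_norm(x, self.params[f"{name}/gain"], self.params[f"{name}/bias"])

    def _gru_cell(self, name: str, x: Tensor, h: Tensor) -> Tensor:
        nh = h.shape[-1]
        gx = x @ self.params[f"{name}/Wx"] + self.params[f"{name}/b"]
        gh = h @ self.params[f"{name}/Wh"]
        z = (gx[:, :nh] + gh[:, :nh]).sigmoid()
        r = (gx[:, nh : 2 * nh] + gh[:, nh : 2 * nh]).sigmoid()
        n = (gx[:, 2 * nh :] + r * gh[:, 2 * nh :]).tanh()
        return (1.0 - z) * n + z * h

    def _lstm_cell(self, name: str, x: Tensor, state) -> tuple[Tensor, Tensor]:
        h, c = state
        nh = h.shape[-1]
        g = x @ self.params[f"{name}/Wx"] + h @ self.params[f"{name}/Wh"] + self.params[f"{name}/b"]
        i = g[:, :nh].sigmoid()
        f = g[:, nh : 2 * nh].sigmoid()
        o = g[:, 2 * nh : 3 * nh].sigmoid()
        gc = g[:, 3 * nh :].tanh()
        c_new = f * c + i * gc
        return o * c_new.tanh(), c_new

    def _recurrent_stack(self, prefix: str, steps: list[Tensor], hidden_sizes, rng, training):
        """Run a GRU/LSTM stack over the step sequence; returns per-step outputs."""
        fam = self.config.block_family
        outputs = steps
        for li, nh in enumerate(hidden_sizes):
            name = f"{prefix}/l{li}"
            b = outputs[0].shape[0]
            h = Tensor(np.zeros((b, nh)))
            c = Tensor(np.zeros((b, nh)))
            new_out = []
            for x in outputs:
                if fam == "gru":
                    h = self._gru_cell(name, x, h)
                    step_out = h
                else:
                    h, c = self._lstm_cell(name, x, (h, c))
                    step_out = h
                step_out = ad.dropout(step_out, self.config.dropout_rate, rng, training)
                new_out.append(self._norm(f"{prefix}/n{li}", step_out))
            outputs = new_out
        return outputs

    def _conv_block(self, prefix: str, x: Tensor, block: int, rng, training) -> Tensor:
        """Encoder convolutional/resnet/multifilter block: conv -> dropout ->
        leaky ReLU -> normalization -> 2x2 max-pool (skip path added before
        the pool output for resnet)."""
        cfg = self.config
        fracs = (0.2, 0.3, 0.4) if cfg.block_family == "multifilter" else (0.3,)
        paths = []
        for frac in fracs:
            w = self.params[f"{prefix}/b{block}/conv{frac}/W"]
            b = self.params[f"{prefix}/b{block}/conv{frac}/b"]
            y = ad.conv2d(x, w, b, stride=1, padding="same")
            y = ad.dropout(y, cfg.dropout_rate, rng, training)
            y = y.leaky_relu(0.01)
            paths.append(y)
        y = paths[0] if len(paths) == 1 else ad.concat(paths, axis=1)
        # normalize over the channel axis
        y = y.transpose(0, 2, 3, 1)
        y = self._norm(f"{prefix}/n{block}", y)
        y = y.transpose(0, 3, 1, 2)
        y = ad.maxpool2d(y, 2, 2)
        if cfg.block_family == "resnet":
            skip = ad.conv2d(
                x,
                self.params[f"{prefix}/b{block}/skip/W"],
                self.params[f"{prefix}/b{block}/skip/b"],
                stride=2,
                padding="same",
            )
            skip = ad.crop2d(skip, y.shape[2], y.shape[3])
            y = y + skip
        return y

    def _conv_decoder_block(self, x: Tensor, block: int, target_hw, rng, training) -> Tensor:
        cfg = self.config
        fracs = (0.2, 0.3, 0.4) if cfg.block_family == "multifilter" else (0.3,)
        paths = []
        for frac in fracs:
            wt = self.params[f"dec/b{block}/tconv{frac}/W"]
            bt = self.params[f"dec/b{block}/tconv{frac}/b"]
            y = ad.conv_transpose2d(x, wt, bt, stride=2)
            y = ad.crop2d(y, target_hw[0], target_hw[1])
            wc = self.params[f"dec/b{block}/conv{frac}/W"]
            bc = self.params[f"dec/b{block}/conv{frac}/b"]
            y = ad.conv2d(y, wc, bc, stride=1, padding="same")
            y = ad.dropout(y, cfg.dropout_rate, rng, training)
            y = y.leaky_relu(0.01)
            paths.append(y)
        y = paths[0] if len(paths) == 1 else ad.concat(paths, axis=1)
        y = y.transpose(0, 2, 3, 1)
        y = self._norm(f"dec/n{block}", y)
        y = y.transpose(0, 3, 1, 2)
        if cfg.block_family == "resnet":
            skip = ad.conv_transpose2d(
                x,
                self.params[f"dec/b{block}/skip/W"],
                self.params[f"dec/b{block}/skip/b"],
                stride=2,
            )
            skip = ad.crop2d(skip, y.shape[2], y.shape[3])
            y = y + skip
        return y

    # -- encoder / decoder / classifier --------------------------------------

    def _encode(self, x: np.ndarray, rng, training) -> Tensor:
        """(B, S, C, Wb, A) -> bottleneck output (B*S, 2L) (step-major)."""
        cfg = self.config
        b, s = x.shape[:2]
        fam = cfg.block_family
        if fam in CONVOLUTIONAL:
            img = Tensor(
                x.reshape(b * s, *self.input_shape).transpose(0, 3, 1, 2)
            )  # (B*S, A, C, Wb)
            y = img
            for i in range(max(cfg.n_layers - 1, 1)):
                y = self._conv_block("enc", y, i, rng, training)
            y = y.reshape(b * s, -1)
            h = self._dense("enc/final", y)
        elif fam == "feedforward":
            y = Tensor(x.reshape(b * s, self.flat_size))
            for i, nh in enumerate(self.encoder_hidden):
                y = self._dense(f"enc/l{i}", y)
                y = ad.dropout(y, cfg.dropout_rate, rng, training)
                y = self._norm(f"enc/n{i}", y)
                y = y.relu()
            h = self._dense("enc/final", y)
        else:  # recurrent: sequence over windows
            steps = [Tensor(x[:, i].reshape(b, self.flat_size)) for i in range(s)]
            outputs = self._recurrent_stack("enc", steps, self.encoder_hidden, rng, training)
            h = ad.stack(outputs, axis=0)  # (S, B, H)
            h = h.transpose(1, 0, 2).reshape(b * s, -1)
            h = self._dense("enc/final", h)
        for d in range(cfg.bottleneck_depth):
            h = self._dense(f"enc/bottleneck{d}", h)
        return h  # (B*S, 2L)

    def _decode(self, z: Tensor, b: int, s: int, rng, training) -> Tensor:
        """latent (B*S, L) -> reconstruction (B, S, C, Wb, A)."""
        cfg = self.config
        fam = cfg.block_family
        if fam in CONVOLUTIONAL:
            n_blocks = max(cfg.n_layers - 1, 1)
            sizes = self._conv_sizes()
            hf, wf = sizes[n_blocks]
            y = self._dense("dec/in", z).reshape(b * s, self._conv_channels, hf, wf)
            for i in range(n_blocks):
                target = sizes[n_blocks - 1 - i]
                y = self._conv_decoder_block(y, i, target, rng, training)
            y = ad.conv2d(
                y, self.params["dec/out/W"], self.params["dec/out/b"], padding="same"
            )
            recon = y.transpose(0, 2, 3, 1)  # (B*S, C, Wb, A)
            return recon.reshape(b, s, *self.input_shape)
        if fam == "feedforward":
            sizes = self.decoder_sizes
            y = self._dense("dec/in", z)
            for i, nh in enumerate(sizes):
                y = self._dense(f"dec/l{i}", y)
                y = ad.dropout(y, cfg.dropout_rate, rng, training)
                y = self._norm(f"dec/n{i}", y)
                y = y.relu()
            y = self._dense("dec/out", y)
            return y.reshape(b, s, *self.input_shape)
        # recurrent decoder: latent sequence drives the mirrored stack
        sizes = self.decoder_sizes
        zsteps = z.reshape(b, s, -1)
        steps = [self._dense("dec/in", zsteps[:, i]) for i in range(s)]
        outputs = self._recurrent_stack("dec", steps, sizes, rng, training)
        out = ad.stack(outputs, axis=0).transpose(1, 0, 2).reshape(b * s, -1)
        out = self._dense("dec/out", out)
        return out.reshape(b, s, *self.input_shape)

    def _classify(self, h: Tensor, b: int, s: int, rng, training):
        cfg = self.config
        logps, ps = [], []
        for j, nj in enumerate(self.dim_sizes):
            if cfg.classifier_family == "lstm":
                hs = h.reshape(b, s, -1)
                steps = [hs[:, i] for i in range(s)]
                hh = Tensor(np.zeros((b, cfg.classifier_hidden)))
                cc = Tensor(np.zeros((b, cfg.classifier_hidden)))
                outs = []
                for x in steps:
                    hh, cc = self._lstm_cell(f"cls/h{j}", x, (hh, cc))
                    outs.append(self._norm(f"cls/n{j}", hh))
                y = ad.stack(outs, axis=0).transpose(1, 0, 2).reshape(b * s, -1)
            else:
                y = self._dense(f"cls/h{j}", h)
                y = ad.dropout(y, cfg.dropout_rate, rng, training)
                y = self._norm(f"cls/n{j}", y)
                y = y.relu()
            logits = self._dense(f"cls/out{j}", y)
            logp = logits.log_softmax(axis=-1)
            logps.append(logp.reshape(b, s, nj))
            ps.append(logp.exp().reshape(b, s, nj))
        return ps, logps

    def forward(
        self, x: np.ndarray, rng: np.random.Generator | None = None, training: bool = False
    ) -> NetworkOutput:
        """Full pass: windows (B, S, C, Wb, A) -> reconstruction, per-dimension
        probabilities, latent sample."""
        if x.shape[2:] != self.input_shape:
            raise ValueError(f"input shape {x.shape[2:]} != configured {self.input_shape}")
        rng = rng or np.random.default_rng(0)
        # masked channels never reach the network
        x = x * self.channel_mask[None, None, :, None, :]
        b, s = x.shape[:2]
        L = self.config.latent_size
        h = self._encode(x, rng, training)
        mu = h[:, :L]
        logvar = h[:, L:]
        z = reparameterized_sample(mu, logvar, rng)
        recon = self._decode(z, b, s, rng, training)
        probs, logps = self._classify(h, b, s, rng, training)
        return NetworkOutput(
            reconstruction=recon,
            class_probs=probs,
            class_logprobs=logps,
            mu=mu.reshape(b, s, L),
            logvar=logvar.reshape(b, s, L),
            z=z.reshape(b, s, L),
        )

    # -- bookkeeping ----------------------------------------------------------

    @property
    def encoder_output_dim(self) -> int:
        return 2 * self.config.latent_size

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def component_params(self, component: str) -> dict[str, Tensor]:
        """Parameters of one component: 'enc', 'dec' or 'cls'."""
        return {k: v for k, v in self.params.items() if k.startswith(component + "/")}

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, v in weights.items():
            self.params[k].data = v.copy()

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def predict_proba(self, windows: np.ndarray, batch_size: int = 256) -> list[np.ndarray]:
        """Deterministic per-dimension probabilities (no dropout, classifier
        reads the deterministic bottleneck output): list of (n, S, Nj)."""
        outs: list[list[np.ndarray]] = [[] for _ in self.dim_sizes]
        for lo in range(0, windows.shape[0], batch_size):
            res = self.forward(windows[lo : lo + batch_size], training=False)
            for j, p in enumerate(res.class_probs):
                outs[j].append(p.data)
        return [np.concatenate(o, axis=0) for o in outs]


def build_network(
    config: ArchitectureConfig,
    input_shape: tuple[int, int, int],
    dim_sizes: list[int],
    seed: int = 0,
) -> Network:
    """Construct the network for windows of shape (C, Wb, A)."""
    return Network(config, input_shape, dim_sizes, seed=seed)
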