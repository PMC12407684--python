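"""Normalization, augmentation, loss closed forms, schedules, optimization."""

import numpy as np
import pytest

from popdecode import train as tr
from popdecode.autodiff import Tensor
from popdecode.model import ArchitectureConfig, Network, NetworkOutput
from popdecode.train import (
    LossWeights,
    Optimizer,
    TrainConfig,
    augment_noise,
    class_weights,
    clip_gradients,
    compute_loss,
    kl_loss,
    lr_schedule,
    normalize_dataset,
    update_lambdas,
)


class TestNormalizeDataset:
    def test_global_mean_zero_and_sd_quarter(self, rng):
        values = rng.standard_normal((12, 6, 40, 4)) * 3 + 1
        mask = np.ones((6, 4), bool)
        out = normalize_dataset(values, mask)
        un = out.transpose(0, 2, 1, 3)[:, :, mask]
        assert abs(un.mean()) < 1e-10
        assert abs(un.std() - 0.25) < 1e-10

    def test_idempotent(self, rng):
        values = rng.standard_normal((8, 4, 30, 2))
        mask = np.ones((4, 2), bool)
        once = normalize_dataset(values, mask)
        twice = normalize_dataset(once, mask)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_most_values_within_half(self, rng):
        values = rng.standard_normal((20, 8, 50, 3))
        mask = np.ones((8, 3), bool)
        out = normalize_dataset(values, mask)
        un = out.transpose(0, 2, 1, 3)[:, :, mask]
        assert (np.abs(un) <= 0.5).mean() >= 0.9

    def test_masked_channels_zero_and_excluded(self, rng):
        values = rng.standard_normal((10, 5, 20, 2))
        mask = np.ones((5, 2), bool)
        mask[0, 0] = False
        values_perturbed = values.copy()
        values_perturbed[:, 0, :, 0] = 1e6  # masked entries must not matter
        a = normalize_dataset(values, mask)
        b = normalize_dataset(values_perturbed, mask)
        np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_array_equal(a[:, 0, :, 0], 0.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normalize_dataset(np.ones((3, 2, 5, 1)), np.ones((2, 1), bool))


class TestAugmentNoise:
    def test_reproducible_given_seed_and_fresh_otherwise(self):
        batch = np.zeros((2, 3, 4, 50, 2))
        a = augment_noise(batch, 5)
        b = augment_noise(batch, 5)
        c = augment_noise(batch, 6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_offset_component_sd(self, monkeypatch):
        """The constant channel-offset component has SD 0.3."""
        monkeypatch.setattr(tr, "WHITE_SD", 0.0)
        monkeypatch.setattr(tr, "WALK_STEP_SD", 0.0)
        batch = np.zeros((100, 1, 100, 1, 1))  # 10^4 channels of length 1x1
        noise = augment_noise(batch, 0, time_bin_ms=1)
        offsets = noise.mean(axis=(1, 3, 4)).ravel()
        assert abs(offsets.std() - 0.3) < 0.01

    def test_spectral_content_below_20hz(self):
        batch = np.zeros((1, 1, 40, 1000, 1))  # one channel, 1000 ms at 1 kHz
        noise = augment_noise(batch, 1, time_bin_ms=1)[0, 0, :, :, 0].ravel()
        # periodogram via rfft at 1 kHz sampling
        power = np.abs(np.fft.rfft(noise - noise.mean())) ** 2
        freqs = np.fft.rfftfreq(noise.size, d=1e-3)
        frac_low = power[freqs <= 20].sum() / power.sum()
        assert frac_low > 0.8


def _fake_output(mu, logvar, recon, probs):
    logps = [Tensor(np.log(np.maximum(p.data, 1e-300))) for p in probs]
    return NetworkOutput(
        reconstruction=recon, class_probs=probs, class_logprobs=logps,
        mu=mu, logvar=logvar, z=mu,
    )


class TestComputeLoss:
    def _perfect(self, b=2, s=1, shape=(2, 3, 1), L=4, dims=(2,)):
        target = np.random.default_rng(0).standard_normal((b, s, *shape))
        labels = np.zeros((b, len(dims)), int)
        probs = []
        for nj in dims:
            p = np.zeros((b, s, nj))
            p[..., 0] = 1.0  # one-hot on the correct class
            probs.append(Tensor(p))
        out = _fake_output(
            mu=Tensor(np.zeros((b, s, L))),
            logvar=Tensor(np.zeros((b, s, L))),  # sigma^2 = 1
            recon=Tensor(target.copy()),
            probs=probs,
        )
        return out, target, labels, dims

    def test_perfect_reconstruction_and_standard_posterior(self):
        out, target, labels, dims = self._perfect()
        w = LossWeights()
        cw = [np.ones(n) for n in dims]
        mask = np.ones((2, 1), bool)
        _, parts = compute_loss(out, target, labels, w, mask, cw)
        assert parts["reconstruction"] == pytest.approx(0.0, abs=1e-12)
        assert parts["kl"] == pytest.approx(0.0, abs=1e-12)
        assert parts["classification"] == pytest.approx(0.0, abs=1e-9)

    def test_kl_unit_shift_is_half(self):
        mu = np.zeros((1, 1, 3))
        mu[..., 0] = 1.0
        val = kl_loss(Tensor(mu), Tensor(np.zeros((1, 1, 3))))
        assert float(val.data) == pytest.approx(0.5)

    def test_kl_matches_monte_carlo_estimate(self):
        """Closed form vs sampling estimate of KL(q || N(0, I)) within 1%."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            L = 4
            mu = rng.uniform(-1, 1, L)
            logvar = rng.uniform(-1, 0.5, L)
            closed = float(kl_loss(Tensor(mu[None]), Tensor(logvar[None])).data)
            sd = np.exp(0.5 * logvar)
            z = rng.standard_normal((10**6, L)) * sd + mu
            log_q = (-0.5 * ((z - mu) / sd) ** 2 - 0.5 * np.log(2 * np.pi) - 0.5 * logvar).sum(1)
            log_p = (-0.5 * z**2 - 0.5 * np.log(2 * np.pi)).sum(1)
            mc = (log_q - log_p).mean()
            assert closed == pytest.approx(mc, rel=0.01)

    def test_masked_channel_contributes_zero_to_reconstruction(self):
        out, target, labels, dims = self._perfect()
        mask = np.ones((2, 1), bool)
        mask[1, 0] = False
        # break the reconstruction only on the masked channel
        out.reconstruction.data[:, :, 1, :, 0] += 50.0
        w = LossWeights()
        cw = [np.ones(n) for n in dims]
        _, parts = compute_loss(out, target, labels, w, mask, cw)
        assert parts["reconstruction"] == pytest.approx(0.0, abs=1e-12)

    def test_non_finite_loss_aborts(self):
        out, target, labels, dims = self._perfect()
        out.reconstruction.data[:] = np.nan
        with pytest.raises(FloatingPointError):
            compute_loss(out, target, labels, LossWeights(), np.ones((2, 1), bool),
                         [np.ones(n) for n in dims])


class TestLossWeights:
    def test_ratio_maintenance_rule(self):
        w = LossWeights(omega=(1.0, 1.0, 0.1))
        update_lambdas(w, (2.0, 1.0, 0.5))
        np.testing.assert_allclose(w.lambdas, [0.5, 1.0, 0.2])
        # weighted components now hold the omega ratio
        assert w.lambdas[0] * 2.0 == pytest.approx(w.lambdas[1] * 1.0)

    def test_equal_priors_equal_omegas_give_equal_lambdas(self):
        w = LossWeights(omega=(1.0, 1.0, 1.0))
        update_lambdas(w, (3.0, 3.0, 3.0))
        assert w.lambdas[0] == w.lambdas[1] == w.lambdas[2]

    def test_doubling_omega_doubles_lambda(self):
        w1 = update_lambdas(LossWeights(omega=(1, 1, 0.1)), (2, 2, 2))
        w2 = update_lambdas(LossWeights(omega=(1, 2, 0.1)), (2, 2, 2))
        assert w2.lambdas[1] == pytest.approx(2 * w1.lambdas[1])

    def test_zero_prior_carries_lambda_over(self):
        w = LossWeights()
        w.lambdas = np.array([7.0, 8.0, 9.0])
        update_lambdas(w, (0.0, 2.0, 1.0))
        assert w.lambdas[0] == 7.0

    def test_printed_rule_is_product(self):
        w = LossWeights(omega=(2.0, 1.0, 1.0), printed_rule=True)
        update_lambdas(w, (3.0, 1.0, 1.0))
        assert w.lambdas[0] == pytest.approx(6.0)


class TestLrSchedule:
    @pytest.mark.parametrize(
        "epoch,expected",
        [(1, 0.2), (3, 0.6), (5, 1.0), (6, 1.0), (30, 1.0), (31, 0.1), (60, 0.1), (61, 0.01)],
    )
    def test_ramp_then_decay(self, epoch, expected):
        assert lr_schedule(epoch, 1.0) == pytest.approx(expected)


class TestGradients:
    def _setup(self, dropout=0.0):
        cfg = ArchitectureConfig(
            block_family="feedforward", n_layers=2, first_layer_size=8,
            latent_size=4, window_width_ms=10, stride_ms=10, time_bin_ms=1,
            dropout_rate=dropout,
        )
        net = Network(cfg, (4, 6, 2), [3], seed=0)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 2, 4, 6, 2))
        labels = rng.integers(0, 3, (8, 1))
        return net, x, labels

    def test_accumulated_gradient_equals_full_batch(self, monkeypatch):
        """Summed sub-batch gradients reproduce the full-batch gradient
        (deterministic forward: dropout off, latent sample pinned to mu)."""
        import popdecode.model as model_mod

        monkeypatch.setattr(
            model_mod, "reparameterized_sample", lambda mu, logvar, rng: mu
        )
        net, x, labels = self._setup()
        mask = np.ones((4, 2), bool)
        cw = [np.ones(3)]
        w = LossWeights()
        g1, _ = tr._batch_gradients(net, x, labels, w, mask, cw,
                                    np.random.default_rng(0), accumulation_steps=1)
        g1 = {k: v.copy() for k, v in g1.items()}
        g4, _ = tr._batch_gradients(net, x, labels, w, mask, cw,
                                    np.random.default_rng(0), accumulation_steps=4)
        for k in g1:
            np.testing.assert_allclose(g1[k], g4[k], atol=1e-10)

    def test_masked_input_perturbation_leaves_gradients_unchanged(self, monkeypatch):
        import popdecode.model as model_mod

        monkeypatch.setattr(
            model_mod, "reparameterized_sample", lambda mu, logvar, rng: mu
        )
        cfg = ArchitectureConfig(
            block_family="feedforward", n_layers=2, first_layer_size=8,
            latent_size=4, window_width_ms=10, stride_ms=10, time_bin_ms=1,
            dropout_rate=0.0,
        )
        mask = np.ones((4, 2), bool)
        mask[3, 1] = False
        net = Network(cfg, (4, 6, 2), [3], seed=0, channel_mask=mask)
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 2, 4, 6, 2))
        labels = rng.integers(0, 3, (4, 1))
        xp = x.copy()
        xp[:, :, 3, :, 1] = 1e3
        cw = [np.ones(3)]
        ga, _ = tr._batch_gradients(net, x, labels, LossWeights(), mask, cw,
                                    np.random.default_rng(0), 1)
        ga = {k: v.copy() for k, v in ga.items()}
        gb, _ = tr._batch_gradients(net, xp, labels, LossWeights(), mask, cw,
                                    np.random.default_rng(0), 1)
        for k in ga:
            np.testing.assert_array_equal(ga[k], gb[k])

    def test_clipping_rescales_only_above_threshold(self):
        g = {"enc/W": np.full(4, 50.0), "dec/W": np.array([3.0, 4.0])}
        out = clip_gradients(g, 100.0)
        np.testing.assert_allclose(np.linalg.norm(out["enc/W"]), 100.0)
        np.testing.assert_array_equal(out["dec/W"], g["dec/W"])

    def test_clipping_is_per_component(self):
        g = {"enc/W": np.full(4, 100.0), "cls/W": np.full(4, 100.0)}
        out = clip_gradients(g, 100.0)
        for k in g:
            assert np.linalg.norm(out[k]) == pytest.approx(100.0)


class TestClassWeights:
    def test_inverse_frequency_ordering(self):
        labels = np.array([[0]] * 90 + [[1]] * 10)
        (w,) = class_weights(labels, [2])
        assert w[1] > w[0] > 0
        assert w[1] / w[0] == pytest.approx(9.0)

    def test_mean_one_normalization(self):
        labels = np.array([[0], [0], [1], [2]])
        (w,) = class_weights(labels, [3])
        assert w.mean() == pytest.approx(1.0)


class TestFitAndSelection:
    def test_fit_improves_on_separable_data_and_selects_best(self):
        rng = np.random.default_rng(0)
        n, s, shape = 60, 3, (4, 6, 2)
        labels = np.stack([rng.integers(0, 3, n)], axis=1)
        x = 0.2 * rng.standard_normal((n, s, *shape))
        x[:, :, 0, :, 0] += labels[:, 0][:, None, None] * 1.5
        cfg = ArchitectureConfig(
            block_family="gru", n_layers=2, first_layer_size=12, latent_size=4,
            window_width_ms=10, stride_ms=10, time_bin_ms=1, dropout_rate=0.1,
        )
        tc = TrainConfig(epochs=12, initial_lr=1e-2, batch_size=16, seed=0, augment=False)
        mask = np.ones((4, 2), bool)
        net, state = tr.fit(x[:40], labels[:40], x[40:], labels[40:], [3], mask, cfg, tc)
        assert state.best_score > 0.5  # well above chance on held-out data
        assert state.best_epoch >= 1
        peaks = [h["val_peak"] for h in state.history]
        assert state.best_score == max(peaks)
        # restored weights reproduce the best validation score
        peak, _ = tr.validation_peak(net, x[40:], labels[40:], [3])
        assert peak == pytest.approx(state.best_score)

    def test_select_best_requires_evaluation(self):
        with pytest.raises(ValueError):
            tr.select_best(tr.TrainState())


class TestCheckpoint:
    def test_round_trip_reproduces_predictions(self, tmp_path, rng):
        from popdecode.train import load_checkpoint, save_checkpoint

        cfg = ArchitectureConfig(
            block_family="gru", n_layers=2, first_layer_size=8, latent_size=4,
            window_width_ms=10, stride_ms=10, time_bin_ms=1, dropout_rate=0.1,
        )
        mask = np.ones((4, 2), bool)
        mask[1, 0] = False
        net = Network(cfg, (4, 6, 2), [3, 2], seed=3, channel_mask=mask)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, net, extra={"epoch": 5})
        back = load_checkpoint(path)
        x = rng.standard_normal((3, 2, 4, 6, 2))
        for a, b in zip(net.predict_proba(x), back.predict_proba(x)):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(back.channel_mask, mask)
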