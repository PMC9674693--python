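import numpy as np
import pytest

from conftest import toy_set
from echotype.denoise import (
    AETrainSpec,
    AutoencoderSpec,
    NoiseSpec,
    augment_training_set,
    build_autoencoder,
    denoise_signal,
    inject_gaussian_noise,
    latent_for_length,
    normalize_signal,
    train_autoencoder,
)
from echotype.io import LabeledSignalSet, SignalRecord


def small_ae_spec(n_samples):
    return AutoencoderSpec(
        latent_dim=latent_for_length(n_samples),
        encoder_filters=(4, 4, 8, 8, 4, 2),
        decoder_filters=(4, 4, 8, 8, 4, 4),
    )


class TestNoiseInjection:
    def test_zero_sigma_is_identity(self):
        x = np.sin(np.linspace(0, 6, 100))
        out = inject_gaussian_noise(x, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out, x)

    def test_empirical_sd_matches_parameter(self):
        x = np.sin(np.linspace(0, 400 * np.pi, 100_000))  # unit peak amplitude
        out = inject_gaussian_noise(x, 0.1, np.random.default_rng(1))
        sd = (out - x).std()
        assert sd == pytest.approx(0.1, rel=0.05)

    def test_deterministic_under_seed(self):
        x = np.ones(50)
        a = inject_gaussian_noise(x, 0.3, np.random.default_rng(5))
        b = inject_gaussian_noise(x, 0.3, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_scale_is_relative_to_peak_amplitude(self):
        x = np.zeros(100_000)
        x[0] = 4.0  # peak 4 -> noise sd 0.1*4
        out = inject_gaussian_noise(x, 0.1, np.random.default_rng(2))
        assert (out - x).std() == pytest.approx(0.4, rel=0.05)


class TestAugmentation:
    def test_ten_copies_gives_elevenfold_set(self):
        sset = toy_set(n_per_class=51, n_samples=8)  # 102 originals
        out = augment_training_set(sset, NoiseSpec(sigma_n=0.1, copies_per_signal=10, seed=0))
        assert len(out) == 1122

    def test_labels_conserved_and_proportions_exact(self):
        sset = toy_set(n_per_class=6, n_samples=8)
        out = augment_training_set(sset, NoiseSpec(copies_per_signal=10, seed=1))
        assert out.class_counts() == {"a": 66, "b": 66}
        parents = {r.id.split("+")[0]: r.label for r in sset.records}
        for rec in out.records:
            assert rec.label == parents[rec.id.split("+")[0]]

    def test_zero_copies_is_identity(self):
        sset = toy_set()
        assert augment_training_set(sset, NoiseSpec(copies_per_signal=0)) is sset

    def test_test_role_rejected(self):
        sset = toy_set()
        sset.role = "test"
        with pytest.raises(ValueError, match="test"):
            augment_training_set(sset, NoiseSpec(copies_per_signal=2))


class TestAutoencoder:
    def test_latent_must_match_compressed_length(self):
        with pytest.raises(ValueError, match="latent_dim"):
            build_autoencoder(AutoencoderSpec(latent_dim=99), 256)

    def test_default_latent_is_1250_for_10000_samples(self):
        assert latent_for_length(10000) == 1250

    def test_bottleneck_smaller_than_signal(self):
        model = build_autoencoder(small_ae_spec(256), 256)
        assert model.spec.latent_dim == 32 < 256

    def test_shape_preserved_and_finite(self):
        model = build_autoencoder(small_ae_spec(250), 250)  # needs padding to 256
        out = denoise_signal(model, np.random.default_rng(0).normal(size=250))
        assert out.shape == (250,)
        assert np.all(np.isfinite(out))

    def test_length_mismatch_rejected(self):
        model = build_autoencoder(small_ae_spec(256), 256)
        with pytest.raises(ValueError, match="length"):
            denoise_signal(model, np.zeros(255))

    def test_inference_deterministic(self):
        model = build_autoencoder(small_ae_spec(128), 128)
        x = np.random.default_rng(1).normal(size=128)
        np.testing.assert_array_equal(denoise_signal(model, x), denoise_signal(model, x))

    def test_training_records_history_and_reduces_loss(self, small_dataset):
        norm = LabeledSignalSet(
            [SignalRecord(r.id, normalize_signal(r.samples), r.label, {}) for r in small_dataset.records[:20]],
            role="train",
        )
        model = train_autoencoder(
            norm, small_ae_spec(512), AETrainSpec(epochs=5, learning_rate=0.003, loss="mse"),
            NoiseSpec(sigma_n=0.1), seed=0,
        )
        assert len(model.training_history) == 5
        assert model.training_history[-1] < model.training_history[0]

    def test_training_on_test_set_rejected(self, small_dataset):
        sset = LabeledSignalSet(list(small_dataset.records), role="test")
        with pytest.raises(ValueError, match="test"):
            train_autoencoder(sset, small_ae_spec(512), AETrainSpec(epochs=1))

    def test_training_deterministic_under_seed(self, small_dataset):
        norm = LabeledSignalSet(
            [SignalRecord(r.id, normalize_signal(r.samples), r.label, {}) for r in small_dataset.records[:10]],
            role="train",
        )
        kw = dict(spec=small_ae_spec(512), tspec=AETrainSpec(epochs=2, learning_rate=0.003),
                  noise=NoiseSpec(sigma_n=0.1), seed=4)
        m1 = train_autoencoder(norm, **kw)
        m2 = train_autoencoder(norm, **kw)
        assert m1.training_history == m2.training_history
        x = normalize_signal(small_dataset.records[0].samples)
        np.testing.assert_array_equal(denoise_signal(m1, x), denoise_signal(m2, x))

    def test_layer_counts_match_architecture(self):
        from echotype import nn

        model = build_autoencoder(small_ae_spec(256), 256)
        conv = [l for l in model.net.layers if isinstance(l, nn.Conv1D)]
        pools = [l for l in model.net.layers if isinstance(l, nn.MaxPool1D)]
        ups = [l for l in model.net.layers if isinstance(l, nn.Upsample1D)]
        dense = [l for l in model.net.layers if isinstance(l, nn.Dense)]
        assert len(conv) == 6 + 7
        assert len(pools) == 3
        assert len(ups) == 3
        assert len(dense) == 2
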