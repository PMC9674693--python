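"""Gaussian-noise corruption/augmentation and the dilated 1D convolutional
denoising autoencoder.

The autoencoder compresses a length-N signal through six dilated 1D
convolutions, three max-poolings and two fully connected layers into a
latent vector Z, then restores it with seven dilated 1D convolutions and
three 2x upsamplings.  Training corrupts each input with fresh zero-mean
Gaussian noise and reconstructs the uncorrupted signal, so the bottleneck
keeps the reproducible structure (the echoes) and discards the noise.

Because the decoder contains no fully connected layer, Z is reshaped to a
length-|Z| single-channel sequence and upsampled 2x three times; this ties
|Z| to N/8 after padding (1250 for the default N = 10000).

The noise scale ``sigma_n`` is relative to a signal normalized to peak
amplitude 1; callers normalize each signal by its maximum absolute value
before denoising (see :func:`normalize_signal`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .io import LabeledSignalSet, SignalRecord


@dataclass
class NoiseSpec:
    sigma_n: float = 0.1
    copies_per_signal: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")
        if self.copies_per_signal < 0:
            raise ValueError("copies_per_signal must be >= 0")


def normalize_signal(samples: np.ndarray) -> np.ndarray:
    """Scale to peak absolute amplitude 1 (identity for all-zero input)."""
    peak = np.max(np.abs(samples))
    return samples / peak if peak > 0 else samples.copy()


def inject_gaussian_noise(samples, sigma_n: float, rng: np.random.Generator, scale: float | None = None):
    """Add i.i.d. N(0, (sigma_n * s)^2) noise; s defaults to the signal's
    peak absolute amplitude so sigma_n reads as a relative level."""
    if sigma_n < 0:
        raise ValueError("sigma_n must be >= 0")
    samples = np.asarray(samples, dtype=float)
    if sigma_n == 0:
        return samples.copy()
    s = np.max(np.abs(samples)) if scale is None else scale
    return samples + rng.normal(0.0, sigma_n * s, size=samples.shape)


def augment_training_set(sset: LabeledSignalSet, noise: NoiseSpec) -> LabeledSignalSet:
    """Originals plus ``copies_per_signal`` noisy replicas, labels conserved.

    Augmentation is a training-time device only; a set tagged as test data
    is refused so no evaluation sample is ever replicated.
    """
    if sset.role == "test":
        raise ValueError("refusing to augment a test set")
    if noise.copies_per_signal == 0:
        return sset
    rng = np.random.default_rng(noise.seed)
    records = []
    for rec in sset.records:
        records.append(rec)
        for j in range(noise.copies_per_signal):
            noisy = inject_gaussian_noise(rec.samples, noise.sigma_n, rng)
            records.append(SignalRecord(f"{rec.id}+n{j}", noisy, rec.label, dict(rec.metadata)))
    return LabeledSignalSet(records, positive_label=sset.positive_label, role=sset.role)


@dataclass
class AutoencoderSpec:
    """Architecture constants; filter/dilation schedules are free choices."""

    latent_dim: int = 1250
    encoder_filters: tuple = (16, 32, 32, 16, 8, 4)
    encoder_dilations: tuple = (1, 2, 4, 8, 16, 32)
    decoder_filters: tuple = (16, 16, 32, 32, 16, 8)
    decoder_dilations: tuple = (1, 2, 4, 8, 16, 32, 1)
    kernel: int = 3
    fc_hidden: int | None = None  # defaults to 2 * latent_dim

    def __post_init__(self):
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be > 0")
        if len(self.encoder_filters) != 6 or len(self.encoder_dilations) != 6:
            raise ValueError("encoder takes 6 conv layers")
        if len(self.decoder_filters) != 6 or len(self.decoder_dilations) != 7:
            raise ValueError("decoder takes 7 conv layers (last one maps to 1 channel)")


@dataclass
class AETrainSpec:
    epochs: int = 200
    learning_rate: float = 0.01
    batch_size: int = 12
    loss: str = "mae"  # "mae" or "mse"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss not in ("mae", "mse"):
            raise ValueError("loss must be 'mae' or 'mse'")


@dataclass
class DenoisingModel:
    spec: AutoencoderSpec
    net: "nn.Sequential"
    n_samples: int
    pad: tuple[int, int]
    training_history: list[float] = field(default_factory=list)


def padded_length(n_samples: int) -> int:
    return ((n_samples + 7) // 8) * 8


def latent_for_length(n_samples: int) -> int:
    """The latent size implied by three 2x poolings of a padded length-N signal."""
    return padded_length(n_samples) // 8


def build_autoencoder(spec: AutoencoderSpec, n_samples: int, seed: int = 0) -> DenoisingModel:
    n_pad = padded_length(n_samples)
    if spec.latent_dim != n_pad // 8:
        raise ValueError(
            f"latent_dim must equal padded_length/8 = {n_pad // 8} for N={n_samples} "
            "(the decoder reshapes Z to a sequence and upsamples 2x three times); "
            "see latent_for_length()"
        )
    hidden = spec.fc_hidden or 2 * spec.latent_dim
    enc_f, enc_d = spec.encoder_filters, spec.encoder_dilations
    layers = []
    for i in range(6):
        layers += [nn.Conv1D(enc_f[i], spec.kernel, enc_d[i]), nn.ReLU()]
        if i % 2 == 1:
            layers.append(nn.MaxPool1D(2))
    layers += [nn.Flatten(), nn.Dense(hidden), nn.ReLU(), nn.Dense(spec.latent_dim)]
    layers.append(nn.Reshape((spec.latent_dim, 1)))
    dec_f, dec_d = spec.decoder_filters, spec.decoder_dilations
    for i in range(6):
        layers += [nn.Conv1D(dec_f[i], spec.kernel, dec_d[i]), nn.ReLU()]
        if i % 2 == 1:
            layers.append(nn.Upsample1D(2))
    layers.append(nn.Conv1D(1, spec.kernel, dec_d[6]))  # linear output, bipolar signals
    net = nn.Sequential(layers, input_shape=(n_pad, 1), seed=seed, dtype=np.float32)
    lo = (n_pad - n_samples) // 2
    return DenoisingModel(spec=spec, net=net, n_samples=n_samples, pad=(lo, n_pad - n_samples - lo))


def _to_batch(model: DenoisingModel, signals: np.ndarray) -> np.ndarray:
    lo, hi = model.pad
    x = np.pad(signals, ((0, 0), (lo, hi)))
    return x[:, :, None]


def train_autoencoder(
    train_set: LabeledSignalSet,
    spec: AutoencoderSpec | None = None,
    tspec: AETrainSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> DenoisingModel:
    """Fit the denoiser on (already normalized) training signals only."""
    if train_set.role == "test":
        raise ValueError("refusing to train the denoiser on a test set")
    tspec = tspec or AETrainSpec()
    noise = noise or NoiseSpec()
    signals = train_set.signal_matrix()
    n = signals.shape[1]
    if spec is None:
        spec = AutoencoderSpec(latent_dim=latent_for_length(n))
    model = build_autoencoder(spec, n, seed=seed)
    targets = _to_batch(model, signals)
    history = nn.fit(
        model.net,
        targets,
        targets,
        loss=tspec.loss,
        epochs=tspec.epochs,
        lr=tspec.learning_rate,
        batch_size=tspec.batch_size,
        seed=seed,
        input_noise_sd=noise.sigma_n,
    )
    model.training_history = history
    return model


def denoise_signal(model: DenoisingModel, samples) -> np.ndarray:
    samples = np.asarray(samples, dtype=float)
    if samples.shape != (model.n_samples,):
        raise ValueError(f"expected a length-{model.n_samples} signal, got {samples.shape}")
    return denoise_batch(model, samples[None, :])[0]


def denoise_batch(model: DenoisingModel, signals: np.ndarray) -> np.ndarray:
    if signals.shape[1] != model.n_samples:
        raise ValueError(f"expected length-{model.n_samples} signals, got {signals.shape}")
    out = model.net.forward(_to_batch(model, signals), train=False)
    lo, _ = model.pad
    return out[:, lo : lo + model.n_samples, 0]
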