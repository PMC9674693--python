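"""YAML/JSON run configuration with validated defaults.

An empty config file yields the library defaults (the best-performing
hyperparameters of the study: autoencoder eps=200, rho=0.01, batch 12,
|Z| relative to N, sigma_n=0.1; CNN rho=0.001, batch 15, eps=50).
Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .classify import ClassifierTrainSpec, Conv1DClassifierSpec, Conv2DClassifierSpec
from .denoise import AETrainSpec, AutoencoderSpec, NoiseSpec, latent_for_length
from .evaluate import PipelineConfig
from .features import ResolutionSpec, STFTSpec
from .simulate import AcquisitionSpec, PulseSpec, ScattererSpec


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PulseConfig(_Block):
    center_frequency: float = 200e6
    fractional_bandwidth: float = Field(0.9, gt=0, lt=2)


class AcquisitionConfig(_Block):
    sample_rate: float = 10e9
    n_samples: int = Field(10000, gt=0)
    film_echo_amplitude: float = 1.0
    film_echo_delay: int = 6000
    scatterer_delay_offset: int = 900
    scatterer_jitter: int = 16
    noise_sd: float = Field(0.05, ge=0)


class ClassConfig(_Block):
    label: str
    diameter: float = Field(gt=0)
    diameter_sd: float = Field(0.0, ge=0)
    material: str = "cell"
    acoustic_contrast: float = Field(1.0, ge=0)


class SimulateConfig(_Block):
    pulse: PulseConfig = PulseConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    classes: list[ClassConfig] = [
        ClassConfig(label="PNT1A", diameter=10.10, diameter_sd=0.88, material="cell"),
        ClassConfig(label="RBC", diameter=6.57, diameter_sd=0.66, material="cell"),
    ]
    n_per_class: int = Field(77, ge=1)


class NoiseConfig(_Block):
    sigma_n: float = Field(0.1, ge=0)
    copies_per_signal: int = Field(10, ge=0)


class AutoencoderConfig(_Block):
    latent_dim: int | None = None  # None -> derived from n_samples
    encoder_filters: list[int] = [16, 32, 32, 16, 8, 4]
    encoder_dilations: list[int] = [1, 2, 4, 8, 16, 32]
    decoder_filters: list[int] = [16, 16, 32, 32, 16, 8]
    decoder_dilations: list[int] = [1, 2, 4, 8, 16, 32, 1]


class AETrainConfig(_Block):
    epochs: int = Field(200, ge=1)
    learning_rate: float = Field(0.01, gt=0)
    batch_size: int = Field(12, ge=1)
    loss: str = "mae"

    @field_validator("loss")
    @classmethod
    def _loss_ok(cls, v):
        if v not in ("mae", "mse"):
            raise ValueError("loss must be 'mae' or 'mse'")
        return v


class ClassifierConfig(_Block):
    filters: list[int] = [16, 16, 32, 32, 64, 64, 128]
    dilations: list[int] = [1, 1, 2, 2, 4, 4, 8]
    dropout_rate: float = Field(0.2, ge=0, lt=1)
    l2: float = Field(1e-4, ge=0)
    epochs: int = Field(50, ge=1)
    learning_rate: float = Field(0.001, gt=0)
    batch_size: int = Field(15, ge=1)


class FeaturesConfig(_Block):
    stft_window: int = Field(32, ge=2)
    stft_step: int = Field(16, ge=1)
    resolution: int | None = None
    resolution_method: str = "decimate"

    @field_validator("resolution_method")
    @classmethod
    def _method_ok(cls, v):
        if v not in ("decimate", "bin-average"):
            raise ValueError("resolution_method must be 'decimate' or 'bin-average'")
        return v


class EvaluationConfig(_Block):
    k: int = Field(3, ge=2)
    positive_label: str | None = None
    threshold: float = 0.5


class RunConfig(_Block):
    seed: int = 0
    representation: str = "spectrum"
    model: str = "cnn1d"
    simulate: SimulateConfig = SimulateConfig()
    noise: NoiseConfig = NoiseConfig()
    autoencoder: AutoencoderConfig = AutoencoderConfig()
    ae_train: AETrainConfig = AETrainConfig()
    classifier: ClassifierConfig = ClassifierConfig()
    features: FeaturesConfig = FeaturesConfig()
    evaluation: EvaluationConfig = EvaluationConfig()

    @field_validator("representation")
    @classmethod
    def _rep_ok(cls, v):
        if v not in ("waveform", "spectrum", "spectrogram"):
            raise ValueError("representation must be waveform|spectrum|spectrogram")
        return v

    @field_validator("model")
    @classmethod
    def _model_ok(cls, v):
        if v not in ("cnn1d", "cnn2d", "svm", "logit", "mlp"):
            raise ValueError("model must be cnn1d|cnn2d|svm|logit|mlp")
        return v

    # --- adapters to library dataclasses -------------------------------

    def pulse_spec(self) -> PulseSpec:
        return PulseSpec(**self.simulate.pulse.model_dump())

    def acquisition_spec(self) -> AcquisitionSpec:
        return AcquisitionSpec(**self.simulate.acquisition.model_dump())

    def class_specs(self) -> list[tuple[str, ScattererSpec]]:
        return [
            (
                c.label,
                ScattererSpec(
                    diameter=c.diameter,
                    diameter_sd=c.diameter_sd,
                    material=c.material,
                    acoustic_contrast=c.acoustic_contrast,
                ),
            )
            for c in self.simulate.classes
        ]

    def pipeline(self) -> PipelineConfig:
        ae = self.autoencoder
        latent = ae.latent_dim or latent_for_length(self.simulate.acquisition.n_samples)
        cls = self.classifier
        return PipelineConfig(
            noise=NoiseSpec(sigma_n=self.noise.sigma_n, copies_per_signal=self.noise.copies_per_signal),
            ae_spec=AutoencoderSpec(
                latent_dim=latent,
                encoder_filters=tuple(ae.encoder_filters),
                encoder_dilations=tuple(ae.encoder_dilations),
                decoder_filters=tuple(ae.decoder_filters),
                decoder_dilations=tuple(ae.decoder_dilations),
            ),
            ae_train=AETrainSpec(**self.ae_train.model_dump()),
            cnn1d_spec=Conv1DClassifierSpec(
                filters=tuple(cls.filters),
                dilations=tuple(cls.dilations),
                dropout_rate=cls.dropout_rate,
                l2=cls.l2,
            ),
            cnn2d_spec=Conv2DClassifierSpec(
                filters=tuple(cls.filters),
                dilations=tuple(cls.dilations),
                dropout_rate=cls.dropout_rate,
                l2=cls.l2,
            ),
            cnn_train=ClassifierTrainSpec(
                epochs=cls.epochs,
                learning_rate=cls.learning_rate,
                batch_size=cls.batch_size,
                seed=self.seed,
            ),
            stft=STFTSpec(window_length=self.features.stft_window, step=self.features.stft_step),
            resolution=(
                ResolutionSpec(self.features.resolution, method=self.features.resolution_method)
                if self.features.resolution
                else None
            ),
            threshold=self.evaluation.threshold,
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) config; empty file -> defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False), encoding="utf-8")
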