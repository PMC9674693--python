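"""Ready-made study configurations.

``paper_scale`` mirrors the acquisition the system was built around
(N = 10000 at 10 GHz, |Z| = 1250, full VGG-style filter widths, 10 noisy
copies per training signal).  ``reduced_scale`` is the configuration used
by this package's own validation experiments: the same pipeline structure
at sizes a single CPU core trains in minutes — 2000-sample records, slimmer
filter schedules, squared-error autoencoder objective with a gentler
learning rate (the full-scale MAE/0.01 recipe needs far more optimizer
steps than the reduced runs take), and 2 noisy copies per training signal.
"""

from __future__ import annotations

from .classify import ClassifierTrainSpec, Conv1DClassifierSpec, Conv2DClassifierSpec
from .denoise import AETrainSpec, AutoencoderSpec, NoiseSpec, latent_for_length
from .evaluate import PipelineConfig
from .simulate import AcquisitionSpec, PulseSpec, ScattererSpec

#: diameter statistics (um) reported for the four object classes
CELL_CLASSES = {
    "PNT1A": dict(diameter=10.10, diameter_sd=0.88, material="cell"),
    "RBC": dict(diameter=6.57, diameter_sd=0.66, material="cell"),
    "bead10": dict(diameter=9.97, diameter_sd=0.07, material="polystyrene"),
    "bead5": dict(diameter=4.98, diameter_sd=0.06, material="polystyrene"),
}


def cell_pair(positive: str = "PNT1A", negative: str = "RBC", contrast=(1.0, 1.0)):
    """Two-class scatterer setup from the named object classes."""
    out = []
    for name, c in zip((positive, negative), contrast):
        kw = dict(CELL_CLASSES[name])
        out.append((name, ScattererSpec(acoustic_contrast=c, **kw)))
    return out


def paper_scale() -> tuple[PulseSpec, AcquisitionSpec, PipelineConfig]:
    return PulseSpec(), AcquisitionSpec(), PipelineConfig()


def reduced_acquisition(n_samples: int = 2000, noise_sd: float = 0.05) -> AcquisitionSpec:
    return AcquisitionSpec(
        n_samples=n_samples,
        film_echo_delay=int(n_samples * 0.6),
        scatterer_delay_offset=int(n_samples * 0.15),
        noise_sd=noise_sd,
    )


def reduced_pipeline(
    n_samples: int = 2000,
    copies_per_signal: int = 2,
    ae_epochs: int = 100,
    cnn_epochs: int = 25,
    seed: int = 0,
) -> PipelineConfig:
    return PipelineConfig(
        noise=NoiseSpec(sigma_n=0.1, copies_per_signal=copies_per_signal),
        ae_spec=AutoencoderSpec(
            latent_dim=latent_for_length(n_samples),
            encoder_filters=(8, 8, 16, 16, 8, 4),
            decoder_filters=(8, 8, 16, 16, 8, 8),
        ),
        ae_train=AETrainSpec(epochs=ae_epochs, learning_rate=0.003, loss="mse"),
        cnn1d_spec=Conv1DClassifierSpec(filters=(8, 8, 16, 16, 32, 32, 64)),
        cnn2d_spec=Conv2DClassifierSpec(filters=(8, 8, 16, 16, 32, 32, 64)),
        cnn_train=ClassifierTrainSpec(epochs=cnn_epochs, seed=seed),
    )
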