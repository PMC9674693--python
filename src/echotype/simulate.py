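"""Parametric forward model for backscattered pulse-echo signals.

Each synthetic recording emulates what the acquisition system sees when a
single micron-sized object is trapped on an acoustically transparent Mylar
film and insonified with a monocycle bipolar pulse: a large film reflection,
a much smaller scatterer echo arriving slightly earlier, and additive
Gaussian instrument noise.  The scatterer echo's amplitude grows with object
diameter and acoustic contrast, and its spectral content softens (lower
low-pass cutoff) as the object grows, so both size and material leave a
signature in the echo.  This is a phenomenological model — no wave
propagation or scattering theory — just enough structure for every
downstream stage to be exercised and validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import LabeledSignalSet, SignalRecord

#: per-material spectral-shaping exponent: cutoff = f_c * (d_ref / d) ** exponent.
#: Softer materials (cells) attenuate high frequencies more steeply than rigid
#: polystyrene, so same-sized objects of different material remain separable.
MATERIAL_SHAPING = {"cell": 0.35, "polystyrene": 0.15}
DEFAULT_SHAPING = 0.25

#: reference diameter (um) for the amplitude law amp ~ contrast * (d/d_ref)**gamma
D_REF_UM = 5.0
AMPLITUDE_EXPONENT = 1.5
#: scatterer-echo amplitude for a reference-diameter, unit-contrast object,
#: relative to the film echo amplitude
BASE_ECHO_GAIN = 0.1


@dataclass
class PulseSpec:
    """Monocycle bipolar excitation pulse.

    ``fractional_bandwidth`` is the -6 dB bandwidth divided by the center
    frequency (the front end's 110-290 MHz band at 200 MHz gives 0.9).
    """

    center_frequency: float = 200e6
    fractional_bandwidth: float = 0.9
    polarity: str = "bipolar"

    def __post_init__(self):
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be > 0")
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional_bandwidth must be in (0, 2)")
        if self.polarity != "bipolar":
            raise ValueError("only bipolar monocycle pulses are modelled")


@dataclass
class ScattererSpec:
    """Population of trapped objects of one class."""

    diameter: float  # um, population mean
    material: str = "cell"
    acoustic_contrast: float = 1.0
    diameter_sd: float = 0.0  # um

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.diameter_sd < 0:
            raise ValueError("diameter_sd must be >= 0")
        if self.acoustic_contrast < 0:
            raise ValueError("acoustic_contrast must be >= 0")


@dataclass
class AcquisitionSpec:
    """Recording geometry and noise level.

    The oscilloscope rate only enters as metadata fixing the pulse's sample
    support; ``n_samples`` sets the recording length N.  Defaults give a
    10000-sample record whose half-spectrum has 5000 non-DC bins.
    """

    sample_rate: float = 10e9
    n_samples: int = 10000
    film_echo_amplitude: float = 1.0
    film_echo_delay: int = 6000
    scatterer_delay_offset: int = 900
    scatterer_jitter: int = 16
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be > 0")
        if not 0 <= self.film_echo_delay < self.n_samples:
            raise ValueError("film_echo_delay outside [0, n_samples)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class EchoSignal:
    samples: np.ndarray
    clean_samples: np.ndarray
    label: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.samples) != len(self.clean_samples):
            raise ValueError("samples and clean_samples must have equal length")
        if not (np.all(np.isfinite(self.samples)) and np.all(np.isfinite(self.clean_samples))):
            raise ValueError("non-finite samples")


def make_monocycle_pulse(pulse: PulseSpec, sample_rate: float, amplitude: float = 1.0) -> np.ndarray:
    """Zero-mean single-cycle bipolar waveform with a Gaussian envelope.

    The envelope width is set from the fractional -6 dB bandwidth, which
    places the magnitude-spectrum peak at the pulse center frequency.
    """
    if sample_rate < 4 * pulse.center_frequency:
        raise ValueError(
            f"sample_rate {sample_rate:g} Hz below the 4x Nyquist margin for a "
            f"{pulse.center_frequency:g} Hz pulse"
        )
    fc = pulse.center_frequency
    sigma_f = pulse.fractional_bandwidth * fc / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    tau = 1.0 / (2.0 * np.pi * sigma_f)
    half = max(1.0 / fc, 4.0 * tau)
    n_half = int(round(half * sample_rate))
    t = np.arange(-n_half, n_half + 1) / sample_rate
    wave = amplitude * np.sin(2.0 * np.pi * fc * t) * np.exp(-(t**2) / (2.0 * tau**2))
    return wave - wave.mean()


def _add_pulse(target: np.ndarray, wave: np.ndarray, center: int) -> None:
    """Add ``wave`` centered at index ``center``, clipping at the edges."""
    half = len(wave) // 2
    lo, hi = center - half, center - half + len(wave)
    s_lo, s_hi = max(0, -lo), len(wave) - max(0, hi - len(target))
    if s_lo >= s_hi:
        return
    target[max(0, lo) : max(0, lo) + (s_hi - s_lo)] += wave[s_lo:s_hi]


def scatterer_echo_waveform(
    scatterer: ScattererSpec, pulse: PulseSpec, sample_rate: float, diameter: float | None = None
) -> np.ndarray:
    """Echo returned by one object: scaled, spectrally shaped pulse."""
    d = scatterer.diameter if diameter is None else diameter
    amp = scatterer.acoustic_contrast * BASE_ECHO_GAIN * (d / D_REF_UM) ** AMPLITUDE_EXPONENT
    wave = make_monocycle_pulse(pulse, sample_rate, amplitude=amp)
    exponent = MATERIAL_SHAPING.get(scatterer.material, DEFAULT_SHAPING)
    cutoff = pulse.center_frequency * (D_REF_UM / d) ** exponent
    cutoff = float(np.clip(cutoff, 0.01 * sample_rate, 0.45 * sample_rate))
    sos = sps.butter(2, cutoff, btype="low", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, wave)


def synthesize_echo(
    scatterer: ScattererSpec,
    acq: AcquisitionSpec,
    pulse: PulseSpec,
    rng: np.random.Generator,
    label: str | None = None,
    diameter: float | None = None,
) -> EchoSignal:
    """One recording: film echo + smaller scatterer echo + Gaussian noise."""
    film = make_monocycle_pulse(pulse, acq.sample_rate, amplitude=acq.film_echo_amplitude)
    jitter = int(rng.integers(-acq.scatterer_jitter, acq.scatterer_jitter + 1)) if acq.scatterer_jitter else 0
    scat_pos = acq.film_echo_delay - acq.scatterer_delay_offset + jitter
    if not 0 <= scat_pos < acq.n_samples:
        raise ValueError(f"scatterer delay {scat_pos} outside [0, {acq.n_samples})")
    echo = scatterer_echo_waveform(scatterer, pulse, acq.sample_rate, diameter=diameter)
    if np.max(np.abs(echo), initial=0.0) >= acq.film_echo_amplitude * np.max(np.abs(film)):
        raise ValueError("scatterer echo would exceed the film reflection; lower the contrast")
    clean = np.zeros(acq.n_samples)
    _add_pulse(clean, film, acq.film_echo_delay)
    _add_pulse(clean, echo, scat_pos)
    noisy = clean + rng.normal(0.0, acq.noise_sd, size=acq.n_samples) if acq.noise_sd > 0 else clean.copy()
    d = scatterer.diameter if diameter is None else diameter
    return EchoSignal(
        samples=noisy,
        clean_samples=clean,
        label=label,
        metadata={
            "material": scatterer.material,
            "diameter_um": float(d),
            "scatterer_position": int(scat_pos),
        },
    )


def _draw_diameter(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd^2) truncated at 0 by redrawing."""
    if sd == 0:
        return mean
    for _ in range(1000):
        d = rng.normal(mean, sd)
        if d > 0:
            return float(d)
    raise RuntimeError("could not draw a positive diameter")


def generate_labeled_dataset(
    classes: list[tuple[str, ScattererSpec]],
    n_per_class: int,
    acq: AcquisitionSpec,
    pulse: PulseSpec,
    seed: int = 0,
    clean: bool = False,
) -> LabeledSignalSet:
    """Balanced labeled dataset with per-signal diameters recorded.

    Each signal gets an independent child generator spawned from ``seed``,
    so regenerating with the same arguments is bit-identical.  ``clean``
    stores the noise-free reference as the record's extra metadata entry.
    """
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    labels = [label for label, _ in classes]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate class labels: {labels}")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(classes) * n_per_class)
    records = []
    idx = 0
    for label, scatterer in classes:
        for i in range(n_per_class):
            rng = np.random.default_rng(children[idx])
            idx += 1
            d = _draw_diameter(rng, scatterer.diameter, scatterer.diameter_sd)
            echo = synthesize_echo(scatterer, acq, pulse, rng, label=label, diameter=d)
            meta = {
                "material": scatterer.material,
                "diameter_um": round(d, 4),
                "seed": seed,
            }
            if clean:
                meta["clean_samples"] = echo.clean_samples
            records.append(SignalRecord(f"{label}-{i:03d}", echo.samples, label, meta))
    return LabeledSignalSet(records)


def scatterer_window(acq: AcquisitionSpec, margin: int = 120) -> slice:
    """Index window around the nominal scatterer-echo position (jitter-safe)."""
    center = acq.film_echo_delay - acq.scatterer_delay_offset
    half = acq.scatterer_jitter + margin
    return slice(max(0, center - half), min(acq.n_samples, center + half))
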