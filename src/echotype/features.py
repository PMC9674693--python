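"""Signal representations: waveform, frequency spectrum, spectrogram.

The spectrum is the magnitude of the discrete Fourier transform over the
non-negative frequencies (the transform of a real signal is conjugate-
symmetric, so the right half carries all information).  The spectrogram is
the squared-magnitude short-time Fourier transform over Hamming-windowed
frames of length ``l`` advanced by ``d`` samples; trailing samples that do
not fill a frame are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Spectrum:
    magnitudes: np.ndarray  # length floor(N/2) + 1, bin 0 = DC
    bin_spacing: float = float("nan")  # Hz, metadata only


@dataclass
class STFTSpec:
    window_length: int = 32
    step: int = 16
    window: str = "hamming"
    magnitude_mode: str = "squared"

    def __post_init__(self):
        if self.window_length < 2:
            raise ValueError("window_length must be >= 2")
        if not 0 < self.step <= self.window_length:
            raise ValueError("step must be in (0, window_length]")
        if self.window != "hamming":
            raise ValueError("only the Hamming window is supported")
        if self.magnitude_mode not in ("squared", "magnitude"):
            raise ValueError("magnitude_mode must be 'squared' or 'magnitude'")


def nine_segment_spec(n_samples: int) -> STFTSpec:
    """Window preset that splits a length-N signal into 9 half-overlapping
    segments (l = N/5 rounded to even, d = l/2)."""
    length = 2 * max(1, round(n_samples / 10))
    return STFTSpec(window_length=length, step=length // 2)


@dataclass
class Spectrogram:
    values: np.ndarray  # (frequency bins, time windows), non-negative


@dataclass
class ResolutionSpec:
    target_bins: int
    method: str = "decimate"  # or "bin-average"

    def __post_init__(self):
        if self.target_bins < 1:
            raise ValueError("target_bins must be >= 1")
        if self.method not in ("decimate", "bin-average"):
            raise ValueError("method must be 'decimate' or 'bin-average'")


def fft_spectrum(samples, sample_rate: float | None = None) -> Spectrum:
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size < 2:
        raise ValueError("need a 1D signal of length >= 2")
    if not np.all(np.isfinite(samples)):
        raise ValueError("non-finite input")
    mags = np.abs(np.fft.rfft(samples))
    spacing = sample_rate / samples.size if sample_rate else float("nan")
    return Spectrum(magnitudes=mags, bin_spacing=spacing)


def stft_spectrogram(samples, spec: STFTSpec | None = None) -> Spectrogram:
    samples = np.asarray(samples, dtype=float)
    spec = spec or STFTSpec()
    n, l, d = samples.size, spec.window_length, spec.step
    if l > n:
        raise ValueError(f"window_length {l} exceeds signal length {n}")
    n_frames = (n - l) // d + 1
    window = np.hamming(l)
    starts = np.arange(n_frames) * d
    frames = samples[starts[:, None] + np.arange(l)] * window
    mags = np.abs(np.fft.rfft(frames, axis=1))
    values = (mags**2 if spec.magnitude_mode == "squared" else mags).T
    return Spectrogram(values=values)


def _decimate_indices(n_source: int, n_target: int) -> np.ndarray:
    return np.round(np.linspace(0, n_source - 1, n_target)).astype(int)


def reduce_resolution(rep, spec: ResolutionSpec):
    """Reduce the frequency axis to ``target_bins`` by subsampling every
    k-th bin (decimate) or by averaging contiguous bin groups."""
    if isinstance(rep, Spectrum):
        axis_len = rep.magnitudes.size
    elif isinstance(rep, Spectrogram):
        axis_len = rep.values.shape[0]
    else:
        raise TypeError("rep must be a Spectrum or Spectrogram")
    if spec.target_bins > axis_len:
        raise ValueError(f"target_bins {spec.target_bins} exceeds source bins {axis_len}")
    if spec.method == "decimate":
        idx = _decimate_indices(axis_len, spec.target_bins)
        if isinstance(rep, Spectrum):
            return Spectrum(rep.magnitudes[idx], rep.bin_spacing)
        return Spectrogram(rep.values[idx])
    if isinstance(rep, Spectrum):
        chunks = np.array_split(rep.magnitudes, spec.target_bins)
        return Spectrum(np.array([c.mean() for c in chunks]), rep.bin_spacing)
    chunks = np.array_split(rep.values, spec.target_bins, axis=0)
    return Spectrogram(np.stack([c.mean(axis=0) for c in chunks]))


def export_spectrogram(spectrogram: Spectrogram, path, delimiter: str = "\t") -> None:
    np.savetxt(path, spectrogram.values, delimiter=delimiter)
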