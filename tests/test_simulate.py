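import numpy as np
import pytest

from echotype.simulate import (
    AcquisitionSpec,
    PulseSpec,
    ScattererSpec,
    generate_labeled_dataset,
    make_monocycle_pulse,
    scatterer_window,
    synthesize_echo,
)


def brute_force_peak_bin(signal):
    """Exhaustive DFT scan: argmax of |sum x[n] e^{-2pi i f n / N}| over half bins."""
    n = len(signal)
    best, best_mag = 0, -1.0
    for f in range(n // 2 + 1):
        mag = abs(np.sum(signal * np.exp(-2j * np.pi * f * np.arange(n) / n)))
        if mag > best_mag:
            best, best_mag = f, mag
    return best


class TestMonocyclePulse:
    def test_spectral_peak_near_center_frequency(self):
        wave = make_monocycle_pulse(PulseSpec(center_frequency=200e6), 10e9)
        padded = np.pad(wave, (0, 4096 - len(wave)))
        peak_hz = np.argmax(np.abs(np.fft.rfft(padded))) * 10e9 / len(padded)
        assert 180e6 <= peak_hz <= 220e6
        assert abs(wave.mean()) < 1e-12

    def test_zero_amplitude_gives_zeros(self):
        wave = make_monocycle_pulse(PulseSpec(), 10e9, amplitude=0.0)
        assert np.all(wave == 0)

    def test_peak_bin_matches_brute_force_dft(self):
        pulse = PulseSpec(center_frequency=100e6)
        wave = make_monocycle_pulse(pulse, 10e9)
        padded = np.pad(wave, (0, 500 - len(wave)))
        fft_bin = int(np.argmax(np.abs(np.fft.rfft(padded))))
        assert fft_bin == brute_force_peak_bin(padded)

    def test_rejects_sampling_below_nyquist_margin(self):
        with pytest.raises(ValueError, match="Nyquist"):
            make_monocycle_pulse(PulseSpec(center_frequency=200e6), 500e6)


class TestSynthesizeEcho:
    def test_zero_contrast_zero_noise_is_pure_film_echo(self, pulse):
        acq = AcquisitionSpec(n_samples=512, film_echo_delay=330, scatterer_delay_offset=150, noise_sd=0.0)
        sc = ScattererSpec(diameter=8.0, acoustic_contrast=0.0)
        echo = synthesize_echo(sc, acq, pulse, np.random.default_rng(0))
        film_only = np.zeros(acq.n_samples)
        wave = make_monocycle_pulse(pulse, acq.sample_rate)
        half = len(wave) // 2
        film_only[acq.film_echo_delay - half : acq.film_echo_delay - half + len(wave)] = wave
        np.testing.assert_allclose(echo.samples, film_only, atol=1e-12)

    def test_identical_seeds_identical_samples(self, pulse, small_acq):
        sc = ScattererSpec(diameter=8.0)
        a = synthesize_echo(sc, small_acq, pulse, np.random.default_rng(7))
        b = synthesize_echo(sc, small_acq, pulse, np.random.default_rng(7))
        assert np.array_equal(a.samples, b.samples)

    def test_scatterer_echo_energy_increases_with_diameter(self, pulse):
        acq = AcquisitionSpec(n_samples=512, film_echo_delay=330, scatterer_delay_offset=150,
                              noise_sd=0.0, scatterer_jitter=0)
        win = scatterer_window(acq)
        energies = []
        for d in (5.0, 7.5, 10.0, 15.0, 20.0):
            echo = synthesize_echo(ScattererSpec(diameter=d), acq, pulse, np.random.default_rng(1))
            energies.append(float(np.sum(echo.clean_samples[win] ** 2)))
        assert all(a < b for a, b in zip(energies, energies[1:]))

    def test_scatterer_peak_below_film_peak(self, pulse, small_acq):
        echo = synthesize_echo(ScattererSpec(diameter=12.0), small_acq, pulse, np.random.default_rng(0))
        win = scatterer_window(small_acq)
        assert np.max(np.abs(echo.clean_samples[win])) < np.max(np.abs(echo.clean_samples))

    def test_out_of_range_scatterer_delay_rejected(self, pulse):
        acq = AcquisitionSpec(n_samples=512, film_echo_delay=100, scatterer_delay_offset=200,
                              scatterer_jitter=0)
        with pytest.raises(ValueError, match="outside"):
            synthesize_echo(ScattererSpec(diameter=8.0), acq, pulse, np.random.default_rng(0))

    def test_noise_variance_matches_specification(self, pulse):
        acq = AcquisitionSpec(n_samples=2048, film_echo_delay=1200, scatterer_delay_offset=300,
                              noise_sd=0.05)
        resid = []
        for i in range(50):
            echo = synthesize_echo(ScattererSpec(diameter=8.0), acq, pulse, np.random.default_rng(i))
            resid.append(echo.samples - echo.clean_samples)
        var = np.concatenate(resid).var()
        assert var == pytest.approx(0.05**2, rel=0.05)


class TestGenerateLabeledDataset:
    def test_counts_77_per_class(self, bead_classes, small_acq, pulse):
        sset = generate_labeled_dataset(bead_classes, 77, small_acq, pulse, seed=3)
        assert len(sset) == 154
        assert sset.class_counts() == {"bead5": 77, "bead10": 77}

    def test_same_seed_identical_datasets(self, bead_classes, small_acq, pulse):
        a = generate_labeled_dataset(bead_classes, 5, small_acq, pulse, seed=9)
        b = generate_labeled_dataset(bead_classes, 5, small_acq, pulse, seed=9)
        assert a.ids == b.ids
        assert np.array_equal(a.signal_matrix(), b.signal_matrix())
        assert [r.metadata for r in a.records] == [r.metadata for r in b.records]

    def test_duplicate_labels_rejected(self, small_acq, pulse):
        spec = ScattererSpec(diameter=5.0)
        with pytest.raises(ValueError, match="duplicate"):
            generate_labeled_dataset([("x", spec), ("x", spec)], 2, small_acq, pulse)

    def test_realized_diameters_recorded_and_positive(self, bead_classes, small_acq, pulse):
        sset = generate_labeled_dataset(bead_classes, 8, small_acq, pulse, seed=5)
        diam = [r.metadata["diameter_um"] for r in sset.records]
        assert all(d > 0 for d in diam)
        assert len(set(diam)) > 1  # population spread actually sampled

    def test_energy_threshold_separates_contrast_ratio_two(self, bead_classes, small_acq, pulse):
        """With a 2x contrast ratio, scatterer-window energy alone classifies >= 90%."""
        sset = generate_labeled_dataset(bead_classes, 30, small_acq, pulse, seed=21)
        win = scatterer_window(small_acq)
        energy = np.array([np.sum(r.samples[win] ** 2) for r in sset.records])
        y = sset.binary_labels()
        thresholds = np.sort(energy)
        best = max(
            max(np.mean((energy >= t) == y), np.mean((energy < t) == y)) for t in thresholds
        )
        assert best >= 0.90
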