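import numpy as np
import pytest

from echotype.io import LabeledSignalSet, SignalRecord
from echotype.simulate import AcquisitionSpec, PulseSpec, ScattererSpec, generate_labeled_dataset


@pytest.fixture(scope="session")
def pulse():
    return PulseSpec()


@pytest.fixture(scope="session")
def small_acq():
    """Short acquisition (512 samples) that keeps every echo in frame."""
    return AcquisitionSpec(n_samples=512, film_echo_delay=330, scatterer_delay_offset=150, noise_sd=0.05)


@pytest.fixture(scope="session")
def bead_classes():
    """Two microsphere populations, twofold acoustic-contrast ratio."""
    return [
        ("bead5", ScattererSpec(diameter=4.98, diameter_sd=0.06, material="polystyrene", acoustic_contrast=1.0)),
        ("bead10", ScattererSpec(diameter=9.97, diameter_sd=0.07, material="polystyrene", acoustic_contrast=2.0)),
    ]


@pytest.fixture(scope="session")
def small_dataset(bead_classes, small_acq, pulse):
    """12 signals per class at N=512; enough for 3-fold pipelines."""
    return generate_labeled_dataset(bead_classes, 12, small_acq, pulse, seed=42)


def toy_set(n_per_class=3, n_samples=16, classes=("a", "b"), seed=0):
    """Hand-rolled labeled set of random short signals (no physics)."""
    rng = np.random.default_rng(seed)
    records = []
    for label in classes:
        for i in range(n_per_class):
            records.append(SignalRecord(f"{label}{i}", rng.normal(size=n_samples), label, {}))
    return LabeledSignalSet(records)
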