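import numpy as np
import pytest

from ramandenoise import (
    LorentzianPeak,
    SimConfig,
    default_axis,
    generate_dataset,
    lorentzian_lineshape,
)


@pytest.fixture(scope="session")
def axis600():
    return default_axis(600)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def single_peak_spectrum(axis600):
    """One on-grid Lorentzian with linewidth = 3 axis steps (FWHM = 6 samples)."""
    step = axis600.step
    center = axis600.values[300]
    peak = LorentzianPeak(amplitude=3 * step, center=center, linewidth=3 * step)
    return lorentzian_lineshape([peak], axis600)


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared by metric/evaluation tests."""
    return generate_dataset(SimConfig(seed=42), 50)


@pytest.fixture(scope="session")
def noisy_pair(small_dataset):
    return small_dataset[0]
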