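import numpy as np
import pytest

from irsom.spectra import ReferenceSet, Spectrum, StructureFractions
from irsom.synthetic import SyntheticModel, make_reference_set


@pytest.fixture
def grid():
    return np.arange(1600.0, 1701.0, 2.0)


@pytest.fixture
def clean_model():
    """Noiseless, jitter-free synthetic band model."""
    return SyntheticModel(noise_sd=0.0, center_jitter_sd=0.0)


@pytest.fixture
def small_refset(clean_model):
    """10 clean synthetic members: fast to train, structure-injective."""
    return make_reference_set(10, clean_model, seed=11)


@pytest.fixture
def noisy_refset():
    return make_reference_set(12, SyntheticModel(), seed=5)


def gaussian(wn, center, amplitude, sigma):
    return amplitude * np.exp(-0.5 * ((wn - center) / sigma) ** 2)


@pytest.fixture
def gaussian_band():
    return gaussian
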