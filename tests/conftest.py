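import numpy as np
import pytest

from streetstat import ica, synth

# Grating frequencies (cycles/pixel) used for the spatial-frequency
# segmentation checks, low to high.
GRATING_FREQS = (0.03, 0.08, 0.16, 0.27, 0.38)


@pytest.fixture(scope="session")
def texture_corpus():
    """Dead-leaves learning corpus shared across the suite."""
    return synth.make_texture_corpus(n_images=40, seed=7)


@pytest.fixture(scope="session")
def natural_bank(texture_corpus):
    """A 16x16 IC filter bank learned from the textured corpus.

    8000 patches keep the suite fast; the learning recipe (tanh
    nonlinearity, 200 iterations, no dimension reduction) is the
    standard one.
    """
    patches = ica.sample_patches(texture_corpus, 8000, patch_size=16, seed=7)
    return ica.learn_filters(patches, iterations=200, seed=7)


@pytest.fixture(scope="session")
def bank_table(natural_bank):
    """Gabor characterization of the session bank (one fit per filter)."""
    return ica.characterize_bank(natural_bank)


@pytest.fixture(scope="session")
def small_bank(texture_corpus):
    """A cheap 8x8 bank for tests that only need a valid bank object."""
    patches = ica.sample_patches(texture_corpus[:6], 1200, patch_size=8, seed=3)
    return ica.learn_filters(patches, iterations=100, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
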