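import numpy as np
import pytest

from lcanet import (Dictionary, LCAParams, LearnConfig, LCAEncoder,
                    make_gabor_dictionary, make_gabor_ground_truth,
                    sample_sparse_patches, standardize, learn_dictionary)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dictionary(rng):
    """Random overcomplete dictionary, P=16, N=32."""
    return Dictionary.from_columns(rng.standard_normal((16, 32)))


@pytest.fixture
def toy_2d_dictionary():
    """Three unit vectors at 0, 60 and 120 degrees in the plane."""
    angles = np.array([0.0, np.pi / 3, 2 * np.pi / 3])
    return Dictionary(np.stack([np.cos(angles), np.sin(angles)]))


@pytest.fixture(scope="session")
def gabor_ground_truth():
    return make_gabor_ground_truth(8, 8, 128, seed=11, noise_sd=0.02)


@pytest.fixture(scope="session")
def trained_dictionary_2x(gabor_ground_truth):
    """2x-overcomplete dictionary learned from generative-model patches.

    Shared across the slower population-level tests; training once keeps the
    whole suite inside a desk-scale runtime.
    """
    patches = standardize(sample_sparse_patches(
        gabor_ground_truth, 5000, 0.05, seed=12))
    init = Dictionary.from_columns(make_gabor_dictionary(8, 8, 128, seed=99))
    return learn_dictionary(
        patches, init,
        LearnConfig(eta=1.0, batch_size=100, n_epochs=120, seed=5),
        LCAParams())


@pytest.fixture(scope="session")
def trained_lca_encoder(trained_dictionary_2x):
    return LCAEncoder(trained_dictionary_2x, LCAParams())
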