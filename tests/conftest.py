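"""Shared fixtures: synthetic datasets and (expensive) AFS computations.

Everything is generated programmatically and cached per session; the small
synthetic (101 channels) keeps the unit-level AFS tests fast while the
full-size default dataset is reserved for the acceptance suite.
"""

import numpy as np
import pytest

import mcrafs as m


@pytest.fixture(scope="session")
def small_config():
    return m.SyntheticConfig(n_channels=101, noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def small_synthetic(small_config):
    """Noiseless 12 x 101 titration dataset with ground truth."""
    return m.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_svd(small_synthetic):
    dataset, _, _ = small_synthetic
    return m.truncated_svd(dataset, 3)


@pytest.fixture(scope="session")
def default_noisy():
    """Full-size dataset at the generator's default noise level."""
    return m.generate_dataset(m.SyntheticConfig())


@pytest.fixture(scope="session")
def default_noiseless():
    return m.generate_dataset(m.SyntheticConfig(noise_sigma=0.0))


@pytest.fixture(scope="session")
def small_region_eps0(small_svd):
    params = m.FeasibilityParams(epsilon=0.0)
    return m.afs_three_component(small_svd, "spectral", params)


@pytest.fixture(scope="session")
def small_region_default_eps(small_svd):
    return m.afs_three_component(small_svd, "spectral", m.FeasibilityParams())


def cosine(a, b):
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
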