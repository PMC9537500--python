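import numpy as np
import pytest

from semipatch.classifier import CnnConfig, build_cnn
from semipatch.synthio import SynthConfig, generate_concept_dataset, generate_patch_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_patches():
    """60 synthetic 32x32 patches, 30 per class."""
    return generate_patch_dataset(SynthConfig(n_per_class=30, seed=7))


@pytest.fixture(scope="session")
def concept_patches():
    return generate_concept_dataset(SynthConfig(seed=11), 40)


@pytest.fixture(scope="session")
def tiny_cnn():
    """A narrow CNN with the standard ladder, random weights."""
    return build_cnn(CnnConfig(conv_kernels=8, fc_widths=(16, 2), seed=0))


@pytest.fixture(scope="session")
def gaussian_scenario():
    """Two 6-sigma-separated Gaussian classes: 100 labelled, 900 unlabelled.

    The Bayes rule (nearest centroid) is the oracle for pseudo-label accuracy.
    """
    rng = np.random.default_rng(42)
    d = 2
    delta = 6.0 / np.sqrt(d)  # centroid distance 6 sigma

    def draw(labels):
        return rng.normal(0.0, 1.0, (len(labels), d)) + np.outer(labels, np.full(d, delta))

    y_lab = np.r_[np.zeros(50, int), np.ones(50, int)]
    X_lab = draw(y_lab)
    y_unlab = rng.integers(0, 2, 900)
    X_unlab = draw(y_unlab)
    centroids = np.stack([np.zeros(d), np.full(d, delta)])
    bayes = np.argmin(((X_unlab[:, None, :] - centroids[None]) ** 2).sum(-1), axis=1)
    return {
        "X_lab": X_lab,
        "y_lab": y_lab,
        "X_unlab": X_unlab,
        "y_unlab": y_unlab,
        "bayes": bayes,
    }
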