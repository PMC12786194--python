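import numpy as np
import pytest

from swarmthresh import Histogram, compute_histogram
from swarmthresh.synthetic import fixture_suite


@pytest.fixture(scope="session")
def suite():
    """The in-memory synthetic fixture suite (one fixed seed per session)."""
    return fixture_suite(seed=1)


@pytest.fixture(scope="session")
def suite_histograms(suite):
    return {name: compute_histogram(rec["image"]) for name, rec in suite.items()}


@pytest.fixture
def two_point_hist():
    """Half the mass at gray level 50, half at 200."""
    probs = np.zeros(256)
    probs[50] = probs[200] = 0.5
    return Histogram(probs=probs, total_pixels=1000)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_histogram(rng, n_levels=256):
    """Random normalized histogram (helper shared by several test modules)."""
    raw = rng.gamma(0.5, size=n_levels)
    return Histogram(probs=raw / raw.sum(), total_pixels=n_levels * 100)
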