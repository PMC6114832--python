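import numpy as np
import pytest

from pseui.segments_io import (
    ALPHABET,
    LabeledDataset,
    RNASegment,
    SyntheticConfig,
    generate_synthetic,
)


def random_segment(rng: np.random.Generator, xi: int) -> RNASegment:
    codes = rng.integers(0, 4, size=2 * xi + 1)
    codes[xi] = 3  # U at center
    return RNASegment("".join(ALPHABET[c] for c in codes), xi)


def random_dataset(rng: np.random.Generator, xi: int, n_pos: int, n_neg: int) -> LabeledDataset:
    segments = [random_segment(rng, xi) for _ in range(n_pos + n_neg)]
    labels = np.array([True] * n_pos + [False] * n_neg)
    return LabeledDataset(segments, labels, xi, name="random")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def biased_dataset():
    """Planted-bias dataset under the standard study conditions (b=0.6, n=200)."""
    return generate_synthetic(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def separable_dataset():
    """Fully planted bias (b=1): classes are essentially separable."""
    return generate_synthetic(SyntheticConfig(n_pos=30, n_neg=30, bias_strength=1.0, seed=5))


@pytest.fixture(scope="session")
def null_dataset():
    """No planted signal: positives and negatives exchangeable."""
    return generate_synthetic(SyntheticConfig(n_pos=50, n_neg=50, bias_strength=0.0, seed=13))
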