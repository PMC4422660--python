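import numpy as np
import pytest

from mldppi import ForestConfig, SyntheticConfig, generate, pair_feature_matrix

#: The reference 22-residue sequence whose full CTD derivation is published,
#: with every printed descriptor value (percent, 2 decimals as printed).
WORKED_SEQUENCE = "GGYCCCYYGYYYGCCGGYYGCG"
WORKED_GROUP_STRING = "1132223313331221133121"
WORKED_COMPOSITION = {1: 36.36, 2: 27.27, 3: 36.36}
WORKED_TRANSITION = {(1, 2): 19.05, (1, 3): 28.57, (2, 3): 9.52}
WORKED_DISTRIBUTION = {
    1: (4.55, 9.09, 59.09, 77.27, 100.0),
    2: (18.18, 18.18, 27.27, 63.64, 95.45),
    3: (13.64, 31.82, 45.45, 54.55, 86.36),
}


def random_region(rng: np.random.Generator, min_len: int = 1, max_len: int = 80) -> np.ndarray:
    """A random group-code region (values 1..7) for oracle comparisons."""
    return rng.integers(1, 8, size=int(rng.integers(min_len, max_len + 1))).astype(np.int8)


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic benchmark: 400 pairs, planted motif signal."""
    records, pairs, manifest = generate(SyntheticConfig(seed=0))
    return records, pairs, manifest


@pytest.fixture(scope="session")
def default_features(default_dataset):
    """Pair feature matrix and labels of the default benchmark (encoded once)."""
    records, pairs, _ = default_dataset
    return pair_feature_matrix(records, pairs)


@pytest.fixture(scope="session")
def small_features():
    """A small (60-pair) planted-signal feature set for fast classifier tests."""
    records, pairs, _ = generate(SyntheticConfig(n_positive=30, n_negative=30, seed=3))
    return pair_feature_matrix(records, pairs)


@pytest.fixture()
def default_forest_config():
    return ForestConfig(n_trees=60, features_per_split=10, seed=0)
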