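import numpy as np
import pytest

from tcrh import SyntheticConfig, apply_filters, featurize_pairs, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """600 planted-rule records, 15 epitopes — shared across test modules."""
    cfg = SyntheticConfig(n_pairs=600, n_unique_epitopes=15, seed=7)
    return apply_filters(generate_dataset(cfg))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """The 192-column feature matrix of the shared small dataset."""
    df = small_dataset.df
    return featurize_pairs(df["epitope"], df["cdr3b"])


@pytest.fixture(scope="session")
def random_sequences():
    """200 seeded random peptide sequences spanning the modelled lengths."""
    rng = np.random.default_rng(20240816)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    return ["".join(rng.choice(alphabet, size=int(rng.integers(8, 24))))
            for _ in range(200)]
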