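import numpy as np
import pytest

from oberisk.fitness import FitnessConfig, SubsetFitness
from oberisk.preprocess import Preprocessor
from oberisk.synthdata import SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest clean synthetic table: 300 rows, 3+3+4 features, 7 classes."""
    spec = SynthSpec(
        n_rows=300,
        relevant_features=["r0", "r1", "r2"],
        n_redundant=3,
        n_noise=4,
        seed=42,
    )
    df, schema, truth = generate_dataset(spec)
    return df, schema, truth


@pytest.fixture(scope="session")
def small_arrays(small_dataset):
    """Preprocessed (X, y) from the small dataset."""
    df, schema, _ = small_dataset
    clean = Preprocessor(schema=schema).fit_transform(df)
    X = clean[schema.feature_names].to_numpy(dtype=float)
    y = clean[schema.label_column].to_numpy(dtype=int)
    return X, y


@pytest.fixture(scope="session")
def small_fitness(small_arrays):
    X, y = small_arrays
    return SubsetFitness(X, y, FitnessConfig(seed=42))


@pytest.fixture(scope="session")
def cached_fitness_table(small_arrays):
    """Exhaustive fitness table over all 2^10 masks of the 10-feature set."""
    from itertools import product

    X, y = small_arrays
    fit = SubsetFitness(X, y, FitnessConfig(seed=42))
    table = {}
    for bits in product([0, 1], repeat=X.shape[1]):
        m = np.array(bits, dtype=np.int8)
        table[bytes(m)] = fit(m) if m.any() else 0.99
    return table
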