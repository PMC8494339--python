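import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mgs.data_io import ExpressionDataset
from mgs.synthetic import SyntheticSpec, generate, separable_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


@pytest.fixture
def toy_fold_lists():
    """Two worked-example selection subsets and their known aggregation."""
    l1 = ["g1", "g3", "g4", "g5", "g6"]
    l2 = ["g1", "g2", "g4", "g6"]
    return l1, l2


@pytest.fixture
def small_dataset(rng):
    """A 12-gene x 30-sample dataset: 3 class-shifted genes plus noise."""
    n = 30
    labels = np.array([0, 1] * (n // 2))
    rows = [rng.normal(size=n) + 2.5 * labels for _ in range(3)]
    rows += [rng.normal(size=n) for _ in range(9)]
    return ExpressionDataset.from_arrays(np.vstack(rows), labels)


@pytest.fixture
def separable():
    return separable_dataset(n_samples=30, n_signal=5, n_noise=15, seed=7)


@pytest.fixture
def tiny_synthetic():
    """A scaled-down generated dataset with every gene role present."""
    spec = SyntheticSpec(n_samples=40, n_informative=4, effect_size=2.0,
                         n_redundant_per_informative=1, n_complementary_pairs=2,
                         n_noise=100, seed=11)
    return generate(spec)
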