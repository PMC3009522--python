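import numpy as np
import pytest

from mfge import ExpressionDataset, SyntheticSpec, generate, make_bank
from mfge.pipeline import preprocess


@pytest.fixture
def tiny_ds():
    """3 genes x 4 samples, 2 classes, hand-written values."""
    return ExpressionDataset(
        ["g1", "g2", "g3"],
        np.array([[0.0, 1.0, 2.0, 3.0],
                  [1.0, 1.0, 2.0, 2.0],
                  [5.0, 5.0, 5.0, 5.0]]),
        ["s1", "s2", "s3", "s4"],
        np.array(["A", "A", "B", "B"]),
    )


@pytest.fixture
def separable_ds():
    """One perfectly separating gene among noise, [0, 1]-scaled."""
    rng = np.random.default_rng(7)
    n = 12
    labels = np.array(["A"] * 6 + ["B"] * 6)
    values = rng.uniform(size=(5, n))
    values[0] = np.where(labels == "A", 0.0, 1.0)
    return ExpressionDataset(
        [f"g{i}" for i in range(5)], values,
        [f"s{i}" for i in range(n)], labels,
    )


@pytest.fixture(scope="session")
def synth_small():
    """Preprocessed 60-gene binary dataset with 6 planted genes."""
    spec = SyntheticSpec(n_genes=60, class_sizes=(15, 15), n_informative=6,
                         effect_size=2.0, seed=11)
    ds, truth = generate(spec)
    return preprocess(ds), truth


@pytest.fixture(scope="session")
def bank():
    return make_bank(seed=0)
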