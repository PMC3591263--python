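import numpy as np
import pytest

from mgforest.data import OmicsDataset, PhenotypeVector, VariableDescriptor


def continuous_dataset(X: np.ndarray, prefix: str = "v",
                       source: str = "transcript") -> OmicsDataset:
    n, m = X.shape
    return OmicsDataset(
        [f"s{i + 1}" for i in range(n)],
        [VariableDescriptor(f"{prefix}{j + 1}", "continuous", source)
         for j in range(m)],
        X,
    )


def phenotype_for(ds: OmicsDataset, y: np.ndarray) -> PhenotypeVector:
    return PhenotypeVector(list(ds.sample_ids), y)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def tiny_dataset(rng):
    """60 samples x 8 variables: v1 drives y, v2 is a near-copy of v1."""
    n = 60
    x1 = rng.normal(size=n)
    x2 = x1 + 0.05 * rng.normal(size=n)
    noise = rng.normal(size=(n, 6))
    X = np.column_stack([x1, x2, noise])
    y = 2.0 * x1 + 0.3 * rng.normal(size=n)
    ds = continuous_dataset(X)
    return ds, phenotype_for(ds, y)
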