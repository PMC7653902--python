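import numpy as np
import pytest

from dtimdn import DTIDataset, SyntheticConfig, generate_synthetic


@pytest.fixture(scope="session")
def block_dataset():
    """The 60x40 four-block planted fixture used across integration tests."""
    return generate_synthetic(SyntheticConfig(seed=1))


@pytest.fixture()
def tiny_dataset():
    """A small handmade binary dataset with exact similarity structure."""
    rng = np.random.default_rng(42)
    n, m = 12, 8
    Y = (rng.random((n, m)) < 0.3).astype(float)
    A = rng.random((n, n))
    SD = np.clip(0.5 * (A + A.T), 0, 1)
    np.fill_diagonal(SD, 1.0)
    B = rng.random((m, m))
    ST = np.clip(0.5 * (B + B.T), 0, 1)
    np.fill_diagonal(ST, 1.0)
    drugs = [f"D{i:03d}" for i in range(n)]
    targets = [f"hsa{j:03d}" for j in range(m)]
    return DTIDataset(drugs, targets, Y, SD, ST, "binary")


def make_random_network(d, seed):
    """A random symmetric network for model-level tests."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(d, d))
    return A + A.T
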