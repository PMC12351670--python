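import numpy as np
import pandas as pd
import pytest

from rhizoclim.io_tables import AsvCountTable
from rhizoclim.synth import GeneratorConfig, generate_all


@pytest.fixture
def tiny_table():
    counts = pd.DataFrame(
        [[1, 2, 3], [4, 5, 6]],
        index=["s1", "s2"], columns=["a1", "a2", "a3"])
    return AsvCountTable(counts=counts)


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic study (no sensor series), shared across tests."""
    return generate_all(GeneratorConfig(seed=7), with_sensors=False)


@pytest.fixture(scope="session")
def dataset_with_sensors():
    return generate_all(GeneratorConfig(seed=7), with_sensors=True)


def make_counts(rng: np.random.Generator, n_samples: int, n_asvs: int,
                depth: int = 2000) -> AsvCountTable:
    """Random multinomial count table for property tests."""
    logits = rng.normal(size=n_asvs)
    comp = np.exp(logits) / np.exp(logits).sum()
    counts = np.vstack([rng.multinomial(depth, comp)
                        for _ in range(n_samples)])
    return AsvCountTable(counts=pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n_samples)],
        columns=[f"a{j}" for j in range(n_asvs)]))
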