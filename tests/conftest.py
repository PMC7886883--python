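import numpy as np
import pandas as pd
import pytest

from amlsubtypes import (ExpressionMatrix, SimulationConfig, simulate_cohorts)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A scaled-down planted scenario for unit tests (3 cohorts, 600 genes,
    a stronger effect than the default so small cohorts stay separable)."""
    return SimulationConfig(n_cohorts=3, samples_per_cohort=(40, 50),
                            n_genes=600, lfc_signature=1.5)


@pytest.fixture(scope="session")
def small_scenario(small_cfg):
    """(count matrices, metadata, truth) for the scaled-down scenario."""
    return simulate_cohorts(small_cfg, seed=7)


@pytest.fixture()
def toy_counts() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[10, 20, 30], [0, 5, 5], [100, 200, 300], [7, 7, 7]],
        index=["g1", "g2", "g3", "g4"], columns=["s1", "s2", "s3"],
    )
    return ExpressionMatrix("toy", values, "raw_counts")


def planted_two_groups(n_per: int = 10, n_genes: int = 40, gap: float = 6.0,
                       seed: int = 0) -> np.ndarray:
    """Samples x features array with two well-separated groups."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per, n_genes))
    b = rng.normal(0.0, 1.0, size=(n_per, n_genes))
    b[:, : n_genes // 2] += gap
    return np.vstack([a, b])
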