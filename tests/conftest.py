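import numpy as np
import pytest

import stemdist as sd


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort shared across read-only tests."""
    return sd.simulate_cohort(sd.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A small cohort for fast structural tests."""
    return sd.simulate_cohort(sd.SyntheticConfig(n_samples=60, n_genes=120, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_expr(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    return sd.ExpressionMatrix(
        gene_ids or [f"g{i}" for i in range(g)],
        sample_ids or [f"s{j}" for j in range(n)],
        values,
    )
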