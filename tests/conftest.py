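import numpy as np
import pytest

from treemosaic import scenarios, simulate_frequencies


@pytest.fixture(scope="session")
def five_pop_tree():
    return scenarios.five_pop_tree(0.1)


@pytest.fixture(scope="session")
def six_pop_tree():
    return scenarios.six_pop_tree()


@pytest.fixture(scope="session")
def coded_rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tree_frequencies(six_pop_tree):
    """Strong-drift frequencies under the six-population tree (shared across
    coded-allele tests)."""
    return simulate_frequencies(six_pop_tree, 20_000, scenarios.ROOT_CODED, seed=42)
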