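import numpy as np
import pytest

from arraybridge.synth import (SimulationConfig, build_scenario,
                               simulate_genotypes)


@pytest.fixture(scope="session")
def small_truth():
    """Small pedigreed truth bundle shared across unit tests."""
    cfg = SimulationConfig(n_founders=10,
                           families=[("F000", "F001", 20)],
                           n_snps=120, n_linkage_groups=2, seed=1)
    return simulate_genotypes(cfg)


@pytest.fixture(scope="session")
def scenario():
    """Mid-size planted-artifact scenario shared across unit tests."""
    return build_scenario(seed=3, n_snps=150, n_founders=48,
                          n_offspring_per_family=25)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
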