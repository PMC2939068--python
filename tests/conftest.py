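import numpy as np
import pytest

from phylodiag.synthetic_data import (
    ParaphylySpec,
    SimConfig,
    simulate_dataset,
    simulate_tree,
    zero_rate_config,
)


@pytest.fixture(scope="session")
def default_config():
    """Study-scale profile: 9 species, 44 + 2 tips, 1348 + 481 columns."""
    return SimConfig(seed=20260930, planted_per_species=3)


@pytest.fixture(scope="session")
def planted_bundle(default_config):
    """Dataset with planted diagnostics over HKY+Gamma background."""
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def clean_bundle(default_config):
    """Same profile with substitution silenced: planted sites only."""
    return simulate_dataset(zero_rate_config(default_config))


@pytest.fixture(scope="session")
def paraphyly_tree():
    cfg = SimConfig(seed=77, paraphyly=ParaphylySpec(host="sp2", embedded="sp5"))
    tree, taxa, truth = simulate_tree(cfg)
    return tree, taxa


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
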