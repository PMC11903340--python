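import numpy as np
import pandas as pd
import pytest

from cresuite import SimConfig, demo_pwms, simulate_catalog, simulate_counts


@pytest.fixture(scope="session")
def pwms():
    return demo_pwms()


@pytest.fixture(scope="session")
def small_config():
    """A small but realistic library used by several cross-module tests."""
    return SimConfig(
        n_promoters=50,
        n_enhancers=150,
        n_shuffled=50,
        n_positive=10,
        barcodes_per_element=(10, 30, 80),
        depth_dna=3e5,
        depth_rna=3e5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_library(small_config, pwms):
    """(catalog, truth) for the small library; generated once per session."""
    return simulate_catalog(small_config, pwms)


@pytest.fixture(scope="session")
def small_counts(small_library, small_config):
    catalog, truth = small_library
    return simulate_counts(catalog, truth, small_config)
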