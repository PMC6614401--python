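import numpy as np
import pytest

import xdosage as xd


@pytest.fixture(scope="session")
def small_fdc_data():
    """A modest fully-dosage-compensated dataset reused across tests."""
    cfg = xd.SimConfig(n_m=3000, n_f=3000, m_x=300, m_causal=30,
                       h2x_f=0.2, pi_escape=0.0, seed=42)
    return xd.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fdc_stats(small_fdc_data):
    d = small_fdc_data
    sm = xd.run_xwas(d.genotypes, d.phenotypes.y_std, xd.MALE)
    sf = xd.run_xwas(d.genotypes, d.phenotypes.y_std, xd.FEMALE)
    return sm, sf


@pytest.fixture(scope="session")
def null_stats():
    """Sex-stratified summary statistics under the global null."""
    cfg = xd.SimConfig(n_m=2000, n_f=2000, m_x=2000, m_causal=0,
                       h2x_f=0.0, seed=9)
    d = xd.simulate_dataset(cfg)
    sm = xd.run_xwas(d.genotypes, d.phenotypes.y_std, xd.MALE)
    sf = xd.run_xwas(d.genotypes, d.phenotypes.y_std, xd.FEMALE)
    return sm, sf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
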