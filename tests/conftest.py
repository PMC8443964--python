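import numpy as np
import pytest

from pleiocca import SimulationConfig, simulate_bundle, simulate_panel
from pleiocca.synthetic_data import simulate_all


@pytest.fixture(scope="session")
def small_cfg():
    """A small but non-trivial simulation: 300 SNPs in 30 LD blocks."""
    return SimulationConfig(
        n_ref=500, n_study_1=1500, n_study_2=1500, n_snps=300, block_size=10,
        rho=0.5, n_pleiotropic=5, n_private_1=5, n_private_2=5,
        effect_size=0.15, pheno_corr=0.2, seed=101,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_all(small_cfg)


@pytest.fixture(scope="session")
def small_panel(small_sim):
    return small_sim["panel"]


@pytest.fixture(scope="session")
def small_bundle(small_cfg, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(small_cfg, outdir)


@pytest.fixture(scope="session")
def null_panel():
    """Independent SNPs (rho = 0), for null-LD checks."""
    cfg = SimulationConfig(n_ref=1000, n_snps=100, rho=0.0, seed=7)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
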