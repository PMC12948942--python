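import numpy as np
import pytest

from triofx.params import VCParams
from triofx import simulate as sim


@pytest.fixture(scope="session")
def mo_config():
    """Small cohort under the adolescent direct+maternal-indirect truth."""
    return sim.SimConfig(
        n_families=300,
        n_snps=400,
        truth=VCParams(sigma2_o=0.088, sigma2_m=0.104, sigma_om=-0.013, sigma2_e=0.82),
        n_timepoints=2,
        sibling_fraction=0.1,
        seed=42,
    )


@pytest.fixture(scope="session")
def mo_cohort(mo_config):
    geno = sim.simulate_trio_genotypes(mo_config)
    effects = sim.draw_effect_vectors(mo_config)
    pheno = sim.simulate_latent_phenotypes(geno, effects, mo_config)
    return geno, effects, pheno


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
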