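import numpy as np
import pytest

from pleioscan import SimConfig, simulate_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_study():
    """3 SNPs x 4 individuals x 2 phenotypes, hard calls, no effect."""
    cfg = SimConfig(n=4, J=2, maf=0.5, n_snps=3, seed=7)
    return simulate_arrays(cfg)


@pytest.fixture
def assoc_study():
    """One causal SNP (effect on phenotype 1 only), n=500, J=3."""
    cfg = SimConfig(
        n=500,
        J=3,
        maf=0.3,
        n_snps=5,
        causal_fraction=1.0,
        forward_effects=np.array([0.4, 0.0, 0.0]),
        imputation_noise=0.05,
        seed=101,
    )
    return simulate_arrays(cfg)


def compound_symmetry(J, rho):
    return (1.0 - rho) * np.eye(J) + rho * np.ones((J, J))
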