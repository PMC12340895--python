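import numpy as np
import pandas as pd
import pytest

from pharmtri import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture(scope="session")
def small_genotypes():
    """2 blocks x 5 variants, 2000 individuals, moderate LD."""
    spec = synth.LdBlockSpec(10, 5, 0.5, maf_range=(0.2, 0.4))
    return synth.simulate_genotypes(spec, 2_000, seed=7)


def toy_region(betas, ses, positions=None, snps=None):
    m = len(betas)
    return pd.DataFrame({
        "SNP": snps or [f"rs{i + 1}" for i in range(m)],
        "POS": positions if positions is not None else np.arange(m) * 100 + 1,
        "BETA": betas,
        "SE": ses,
    })
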