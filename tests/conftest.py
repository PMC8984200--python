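import numpy as np
import pandas as pd
import pytest

import keelscan as ks


@pytest.fixture(scope="session")
def trio_pedigree():
    """Sire, dam and one offspring."""
    return pd.DataFrame({"id": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2]})


@pytest.fixture(scope="session")
def random_pedigree():
    """A 500-individual pedigree from the half-sib generator."""
    cfg = ks.QuantGenConfig(n_founders=120, n_generations=3, family_size=2, seed=42)
    ped, _ = ks.simulate_pedigree_phenotypes(cfg)
    return ped.head(500).copy()


@pytest.fixture(scope="session")
def neutral_counts():
    """10k neutral sites at background differentiation 0.05."""
    cfg = ks.SimConfig(
        n_chrom=1, chrom_length=20_000_000, n_snps=10_000, background_fst=0.05, seed=101
    )
    return ks.simulate_pool_counts(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
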