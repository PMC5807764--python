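import numpy as np
import pytest

from phylocorridor import (
    GeneticSimConfig,
    HaplotypeDataset,
    LandscapeConfig,
    make_haplotype_chain,
    sample_populations,
)
from phylocorridor.simulate import PANMIXIA


@pytest.fixture
def chain8():
    return make_haplotype_chain(8, 40, seed=1)


@pytest.fixture
def panmictic_dataset(chain8):
    cfg = GeneticSimConfig(
        n_pops=10, n_ind_per_pop=20, n_haplotypes=8, structure_sigma=PANMIXIA, seed=7
    )
    return sample_populations(chain8, cfg)


@pytest.fixture
def structured_dataset():
    chain = make_haplotype_chain(10, 40, seed=2)
    cfg = GeneticSimConfig(
        n_pops=10, n_ind_per_pop=20, n_haplotypes=10, structure_sigma=1.0, seed=11
    )
    return sample_populations(chain, cfg), chain


@pytest.fixture
def two_fixed_pops():
    """Two populations each fixed for a different haplotype (n = 5 each)."""
    return HaplotypeDataset(
        haplotype_ids=["H1", "H2"],
        sequences={"H1": "AAAA", "H2": "AAAT"},
        counts=np.array([[5, 0], [0, 5]]),
        pop_ids=["P1", "P2"],
    )


@pytest.fixture
def landscape_config():
    return LandscapeConfig(
        n_rows=20, n_cols=60, band_row_center=10, band_half_width=2,
        band_suitability=0.9, background_suitability=0.1, noise_sd=0.0, seed=0,
    )
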