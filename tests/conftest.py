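import numpy as np
import pytest

from pleiomap import synthdata
from pleiomap.synthdata import SyntheticConfig


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_regions=20, n_genes=400, n_subjects=300, seed=11)


@pytest.fixture(scope="session")
def geometry(small_config):
    return synthdata.gen_parcellation(small_config)


@pytest.fixture(scope="session")
def annotations(small_config):
    return synthdata.gen_gene_annotations(small_config)


@pytest.fixture(scope="session")
def assoc_data(small_config, geometry, annotations):
    """(zmats, disorder, truth) for the small synthetic study."""
    return synthdata.gen_gene_assoc(small_config, geometry, annotations)


@pytest.fixture(scope="session")
def phenotypes(small_config, geometry):
    tables, truth = synthdata.gen_phenotypes(small_config, geometry)
    return tables, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
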