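import numpy as np
import pandas as pd
import pytest

from gutflow.containers import AbundanceMatrix
from gutflow.simulate import (
    SimulationConfig,
    generate_gene_study,
    generate_metabolome_study,
    generate_taxon_study,
)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def gene_study(default_config):
    return generate_gene_study(default_config)


@pytest.fixture(scope="session")
def taxon_study(default_config):
    return generate_taxon_study(default_config)


@pytest.fixture(scope="session")
def metabolome_study(default_config, taxon_study):
    return generate_metabolome_study(default_config, taxon_study)


@pytest.fixture(scope="session")
def meta(default_config):
    return default_config.metadata()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_relative():
    data = pd.DataFrame(
        {
            "s1": [0.5, 0.25, 0.25],
            "s2": [0.2, 0.3, 0.5],
            "s3": [0.1, 0.1, 0.8],
        },
        index=["Bacteroides", "Prevotella", "Faecalibacterium"],
    )
    return AbundanceMatrix(data, kind="relative")
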