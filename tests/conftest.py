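import numpy as np
import pytest

from potatosim import datasets
from potatosim.synthetic import SyntheticConfig, generate_trial

GENOTYPES = ("Yunshu 401", "Yunshu 505", "Cooperation 88")


@pytest.fixture(scope="session")
def climates():
    return {s: datasets.load_climate(s) for s in datasets.SEASONS}


@pytest.fixture(scope="session")
def crop_sets():
    """All nine genotype × season parameter sets with phenology."""
    out = {}
    for season in datasets.SEASONS:
        for g in GENOTYPES:
            out[(season, g)] = (
                datasets.load_crop_parameters(season, g),
                datasets.load_phenology(season, g),
            )
    return out


@pytest.fixture(scope="session")
def default_trial():
    return generate_trial(SyntheticConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
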