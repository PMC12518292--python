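import numpy as np
import pandas as pd
import pytest

from phenocae.imaging import PlotImage
from phenocae.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def tiny_dataset():
    """8 genotypes x 5 environments x 2 replicates, default chip shape."""
    return simulate_dataset(SimulationConfig(n_genotypes=8, seed=7))


@pytest.fixture(scope="session")
def tiny_config():
    return SimulationConfig(n_genotypes=8, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_image(pixels, plot_id="P1", **kwargs):
    defaults = dict(genotype_id="G001", environment_id="E1", replicate_id=1)
    defaults.update(kwargs)
    return PlotImage(pixels=np.asarray(pixels, dtype=float), plot_id=plot_id, **defaults)
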