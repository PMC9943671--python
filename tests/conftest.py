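import numpy as np
import pytest

from nanoladder import ChannelConfig, assign_codebook
from nanoladder.simulate import DEFAULT_GENE_PANEL, GeneModel, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def nineplex_codebook():
    """Two detection channels x three repeat levels, nine-gene panel."""
    return assign_codebook(list(DEFAULT_GENE_PANEL), ChannelConfig(2, 3))


@pytest.fixture
def ladder_config():
    """Single-channel 1-10 DFP ladder, max-normalized, equal brightness."""
    return ChannelConfig(n_detection_channels=1, n_levels=10)


@pytest.fixture
def small_sim_config():
    """A light simulation: few cells, modest expression, image-friendly."""
    return SimulationConfig(
        seed=7,
        n_cells=4,
        genes={g: GeneModel(mean=8.0) for g in DEFAULT_GENE_PANEL},
    )


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))
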