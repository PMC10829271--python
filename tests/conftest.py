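import numpy as np
import pytest

from demux2kit import ClassifyConfig, SimulationConfig, demultiplex, simulate_tags


@pytest.fixture(scope="session")
def low_noise_sim():
    """Small 4-tag simulation with low contamination and a few doublets."""
    cfg = SimulationConfig(
        n_tags=4,
        cells_per_tag_meanlog=5.5,
        cells_per_tag_sdlog=0.2,
        contamination_range=(0.005, 0.015),
        ambient_range=(0.5, 2.0),
        doublet_fraction=0.05,
        seed=11,
    )
    return simulate_tags(cfg)


@pytest.fixture(scope="session")
def moderate_sim():
    """10-tag, ~11k-cell simulation at the moderate default noise level."""
    cfg = SimulationConfig(
        n_tags=10, cells_per_tag_meanlog=7.0, cells_per_tag_sdlog=0.4, seed=23
    )
    return simulate_tags(cfg)


@pytest.fixture(scope="session")
def low_noise_result(low_noise_sim):
    matrix, _ = low_noise_sim
    return demultiplex(matrix, ClassifyConfig(seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
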