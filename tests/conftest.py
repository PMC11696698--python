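import numpy as np
import pytest

from spotdeconv import (
    ReferenceProfile,
    SimulationConfig,
    SpatialExpression,
    align_genes,
    generate_dataset,
    preprocess,
)


@pytest.fixture
def tiny_ref():
    """Six cells, four genes, two types; g2 is exclusive to type A."""
    counts = np.array(
        [
            [5.0, 1.0, 9.0, 1.0],
            [4.0, 1.0, 8.0, 1.0],
            [6.0, 1.0, 10.0, 1.0],
            [5.0, 1.0, 0.0, 1.0],
            [4.0, 1.0, 0.0, 1.0],
            [6.0, 1.0, 0.0, 1.0],
        ]
    )
    return ReferenceProfile(
        counts=counts,
        gene_ids=np.array(["g0", "g1", "g2", "g3"]),
        cell_types=np.array(["A", "A", "A", "B", "B", "B"]),
    )


@pytest.fixture
def tiny_spatial():
    counts = np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]])
    return SpatialExpression(
        counts=counts,
        gene_ids=np.array(["g0", "g1", "g2", "g3"]),
        coordinates=np.array([[0.0, 0.0], [1.0, 1.0]]),
    )


@pytest.fixture(scope="session")
def noiseless_data():
    """Default-scale noiseless mixture: the linear model holds exactly."""
    cfg = SimulationConfig(noise_model="none", seed=11)
    ref, spatial, truth = generate_dataset(cfg)
    return ref, spatial, truth


@pytest.fixture(scope="session")
def noiseless_preprocessed(noiseless_data):
    ref, spatial, truth = noiseless_data
    ref2, sp2 = preprocess(*align_genes(ref, spatial))
    return ref2, sp2, truth


@pytest.fixture(scope="session")
def poisson_data():
    cfg = SimulationConfig(noise_model="poisson", seed=7)
    ref, spatial, truth = generate_dataset(cfg)
    return ref, spatial, truth
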