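import numpy as np
import pytest

from labkg import (
    BandParams,
    ReferenceRange,
    TrainConfig,
    build_graph,
    train,
)


@pytest.fixture(scope="session")
def coarse_ranges():
    """Two indicators with coarse grids -> a small graph (< 50 entities)."""
    return [
        ReferenceRange("alpha", 1.0, 2.0, units="u", grid_step=0.5),
        ReferenceRange("beta", 4.0, 6.0, units="w", grid_step=1.0),
    ]


@pytest.fixture(scope="session")
def coarse_graph(coarse_ranges):
    return build_graph(coarse_ranges, BandParams(0.25, 0.75))


@pytest.fixture(scope="session")
def tiny_trained(coarse_graph):
    """TransH trained briefly on the coarse graph, for encoder tests."""
    catalog, triples = coarse_graph
    params = train(
        "transH", triples, catalog,
        TrainConfig(epochs=120, batch_size=8, seed=11), dim_k=8,
    )
    return catalog, triples, params


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
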