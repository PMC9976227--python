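import numpy as np
import pandas as pd
import pytest

from supplynet.trade_data import TradeNetwork, clean_flows
from supplynet.synthetic_world import WorldConfig, generate_world


def make_flows(records):
    """(year, exporter, importer, value) tuples -> validated TradeFlowTable."""
    frame = pd.DataFrame(records,
                         columns=["year", "exporter", "importer", "value"])
    return clean_flows(frame)


def make_network(adj, year=2019, nodes=None):
    """Dense adjacency (list-of-lists or ndarray) -> TradeNetwork."""
    w = np.asarray(adj, dtype=float)
    nodes = nodes or [chr(ord("A") + i) for i in range(w.shape[0])]
    return TradeNetwork(year=year, nodes=list(nodes), weights=w)


@pytest.fixture
def tiny_flows():
    return make_flows([
        (2019, "AAA", "BBB", 2.0e8),
        (2019, "AAA", "CCC", 0.6e8),
        (2019, "BBB", "CCC", 1.5e8),
        (2019, "CCC", "AAA", 0.9e8),
    ])


@pytest.fixture(scope="session")
def world_pre():
    return generate_world(WorldConfig(n_countries=80, seed=11,
                                      cri_regime="pre_epidemic"))


@pytest.fixture(scope="session")
def world_epidemic():
    return generate_world(WorldConfig(n_countries=80, seed=11,
                                      cri_regime="epidemic"))
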