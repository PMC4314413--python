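import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from hubnet import synthetic_data as sd

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture
def path_graph() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


@pytest.fixture
def star_graph() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from(("hub", f"leaf{i}") for i in range(5))
    return g


@pytest.fixture(scope="session")
def sim_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def sim_bundle(sim_config):
    """One fully generated simulation shared across tests."""
    studies, truth = sd.generate_studies(sim_config)
    universe = sd.gene_universe(sim_config)
    net, truth = sd.generate_network(sim_config, universe, truth)
    pathways, truth = sd.generate_pathways(sim_config, universe, truth)
    return {
        "config": sim_config,
        "studies": studies,
        "universe": universe,
        "network": net,
        "pathways": pathways,
        "truth": truth,
    }
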