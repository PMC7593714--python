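import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from herbnet import datasets, demo


@pytest.fixture(scope="session")
def table1_components():
    """The packaged 11-compound ADME table."""
    return datasets.load_pinellia_components()


@pytest.fixture(scope="session")
def table2_grid():
    """The packaged disease-target grid (raw, duplicates included)."""
    return datasets.load_asthma_target_table()


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """Fixture-seeded input bundle shared across pipeline tests."""
    return demo.make_demo_bundle(tmp_path_factory.mktemp("bundle"), seed=7)


def random_graphs(n_graphs: int, max_nodes: int = 25, seed0: int = 0):
    """Deterministic family of small test graphs of varied size and density."""
    for i in range(n_graphs):
        n = 2 + (i * 7 + seed0) % (max_nodes - 1)
        p = (0.05, 0.15, 0.3, 0.6)[i % 4]
        g = nx.gnp_random_graph(n, p, seed=seed0 + i)
        if i % 5 == 0:
            g.add_node(n)  # ensure isolated nodes appear regularly
        yield g
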