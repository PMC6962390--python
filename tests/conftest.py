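import networkx as nx
import pytest

from ccpalink.synthetic import fixture_g5


@pytest.fixture
def g5() -> nx.Graph:
    """Five-node fixture: triangle A-B-C with tail C-D-E."""
    return fixture_g5()


def seeded_er_graphs(count: int, n: int = 14, seed0: int = 100, p_lo: float = 0.08, p_hi: float = 0.38):
    """Deterministic battery of Erdos-Renyi graphs spanning sparse to dense."""
    graphs = []
    for i in range(count):
        p = p_lo + (p_hi - p_lo) * ((i % 7) / 6)
        graphs.append(nx.gnp_random_graph(n, p, seed=seed0 + i))
    return graphs
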