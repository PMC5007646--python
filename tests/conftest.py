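import networkx as nx
import pytest

from driverscan.network import Network


def net_from_edges(pairs) -> Network:
    """Build a Network directly from (a, b) symbol pairs."""
    g = nx.Graph()
    g.add_edges_from(pairs)
    nx.set_edge_attributes(g, 1.0, "score")
    return Network(genes=tuple(sorted(g.nodes)), graph=g)


@pytest.fixture
def star_net():
    """Star graph: center C with leaves L1..L5."""
    return net_from_edges([("C", f"L{i}") for i in range(1, 6)])


@pytest.fixture
def path_net():
    """Path graph P0 - P1 - ... - P6."""
    return net_from_edges([(f"P{i}", f"P{i+1}") for i in range(6)])


@pytest.fixture
def toy_network_path(tmp_path):
    """A copy of the packaged toy edge list on disk."""
    from importlib import resources

    ref = resources.files("driverscan.data") / "toy_network.tsv"
    dst = tmp_path / "toy_network.tsv"
    dst.write_text(ref.read_text(encoding="utf-8"), encoding="utf-8")
    return dst
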