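import io

import networkx as nx
import pytest

from netpharm.network import build_network, read_string_tsv
from netpharm.synthetic import SynthSpec, synth_ppi
from netpharm.targets import classify_nodes


def graph_from_edges(pairs):
    """Categorize every endpoint as drug-only and build the network."""
    g = nx.Graph()
    g.add_edges_from(pairs)
    for n in g.nodes():
        g.nodes[n]["category"] = "drug_only"
    return g


@pytest.fixture
def planted_network():
    """One planted-partition instance read through the TSV path, plus truth."""
    spec = SynthSpec(seed=11)
    tsv, truth = synth_ppi(spec)
    edges = read_string_tsv(io.StringIO(tsv))
    symbols = {a for a, _, _ in edges} | {b for _, b, _ in edges}
    network = build_network(edges, classify_nodes(symbols, set()))
    planted = frozenset(truth.loc[truth.planted_module == 0, "gene_symbol"])
    return network, planted
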