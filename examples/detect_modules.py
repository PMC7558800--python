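"""Detect dense modules in a synthetic interactome with one planted block.

A planted-partition graph (200 genes, one 20-gene block wired at p=0.6 over
a p=0.02 background) is emitted as a STRING-style TSV, read back, and
clustered. The top module's score is density x node count (2E/(N-1)); the
Jaccard index says how exactly the detected module matches the planted one.
"""

import io

from netpharm import find_modules
from netpharm.mcode import module_table
from netpharm.network import build_network, read_string_tsv
from netpharm.synthetic import SynthSpec, synth_ppi
from netpharm.targets import classify_nodes

spec = SynthSpec(seed=11)
tsv, truth = synth_ppi(spec)
edges = read_string_tsv(io.StringIO(tsv))
symbols = {a for a, _, _ in edges} | {b for _, b, _ in edges}
network = build_network(edges, classify_nodes(symbols, set()))

modules = find_modules(network)
print(module_table(modules).drop(columns="members").to_string(index=False))

planted = set(truth.loc[truth.planted_module == 0, "gene_symbol"])
top = set(modules[0].members)
jaccard = len(top & planted) / len(top | planted)
print(f"\ntop module vs planted 20-gene block: Jaccard = {jaccard:.2f}")
print("(1.0 means the dense block was recovered exactly)")
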