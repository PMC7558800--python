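"""Molecular Complex Detection (MCODE) — density-based module detection.

A from-scratch implementation of the classic seed-and-grow algorithm for
finding densely connected regions ("clusters" or molecular complexes) in a
protein–protein interaction network:

1. **Vertex weighting.** Each node *v* is weighted by the densest k-core of
   the subgraph induced on its closed neighborhood: weight = k × density of
   that k-core, with loop-free density 2E / (N(N−1)). Nodes with degree
   below ``degree_cutoff`` get weight 0.
2. **Complex prediction.** Starting from the highest-weight unvisited node,
   a depth-limited outward traversal admits an unvisited neighbor when its
   weight is at least ``(1 − node_score_cutoff)`` times the weight of the
   node being expanded, so the complex follows the local weight gradient
   from the seed outward. Admitted nodes are marked visited, so core
   members of different modules never overlap.
3. **Post-processing.** Candidates lacking a ``k_core_filter``-core are
   discarded. ``haircut`` iteratively strips members with fewer than two
   in-module neighbors (equivalently: keeps the candidate's 2-core).
   ``fluff`` optionally adds boundary nodes whose closed-neighborhood
   density exceeds ``fluff_threshold``; fluffed nodes may repeat across
   modules and do not enter the score.

The module score is density × node count = 2E/(N−1), the quantity reported
in standard cluster tables (to three decimals).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "McodeParams",
    "DetectedModule",
    "core_decomposition",
    "vertex_weight",
    "vertex_weights",
    "find_modules",
    "module_score",
    "score_from_counts",
    "module_table",
]


@dataclass(frozen=True)
class McodeParams:
    """MCODE tuning parameters (defaults are the published plugin defaults)."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core_filter: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_threshold: float = 0.1
    max_depth: int = 100

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0:
            raise ValueError("degree_cutoff must be >= 0")
        if not (0.0 <= self.node_score_cutoff < 1.0):
            raise ValueError("node_score_cutoff must lie in [0, 1)")
        if self.k_core_filter < 0:
            raise ValueError("k_core_filter must be >= 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class DetectedModule:
    """One detected complex: core members, seed, counts and score."""

    members: frozenset[str]
    seed: str
    n_nodes: int
    n_edges: int
    score: float
    fluffed: frozenset[str] = field(default_factory=frozenset)


def core_decomposition(network: nx.Graph) -> dict[str, int]:
    """Core number of every node: the largest k such that the node survives
    in a maximal subgraph of minimum degree k."""
    return nx.core_number(network)


def _density(n_nodes: int, n_edges: int) -> float:
    # loop-free density: fraction of the N(N-1)/2 possible edges present
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def vertex_weight(network: nx.Graph, v: str, degree_cutoff: int = 2) -> float:
    """MCODE weight of node ``v``: k × density of the densest k-core of the
    closed-neighborhood subgraph; 0 for nodes below the degree cutoff."""
    if network.degree(v) < degree_cutoff:
        return 0.0
    closed = list(network.neighbors(v)) + [v]
    h = network.subgraph(closed)
    cores = nx.core_number(h)
    k = max(cores.values())
    core_nodes = [n for n, c in cores.items() if c >= k]
    hk = h.subgraph(core_nodes)
    return k * _density(hk.number_of_nodes(), hk.number_of_edges())


def vertex_weights(network: nx.Graph, degree_cutoff: int = 2) -> dict[str, float]:
    return {v: vertex_weight(network, v, degree_cutoff) for v in network.nodes()}


def _grow(
    network: nx.Graph,
    seed: str,
    weights: dict[str, float],
    visited: set[str],
    score_cutoff: float,
    max_depth: int,
) -> set[str]:
    # breadth-first outward traversal, depth-limited; a neighbor is admitted
    # when its weight keeps within score_cutoff of the expanding node's
    # weight, letting the complex follow the local weight gradient
    members = {seed}
    queue: deque[tuple[str, int]] = deque([(seed, 0)])
    while queue:
        node, depth = queue.popleft()
        if depth >= max_depth:
            continue
        admit_at = weights[node] * (1.0 - score_cutoff)
        for nb in network.neighbors(node):
            if nb in members or nb in visited:
                continue
            if weights[nb] >= admit_at:
                members.add(nb)
                queue.append((nb, depth + 1))
    return members


def _haircut(subgraph: nx.Graph) -> set[str]:
    """Iteratively remove members with < 2 in-module neighbors (= 2-core)."""
    g = nx.Graph(subgraph)
    changed = True
    while changed:
        drop = [n for n, d in g.degree() if d < 2]
        changed = bool(drop)
        g.remove_nodes_from(drop)
    return set(g.nodes())


def find_modules(network: nx.Graph, params: McodeParams | None = None) -> list[DetectedModule]:
    """Detect density-based modules, returned by score descending.

    Ties break by size descending, then by seed symbol; seed selection and
    traversal are fully deterministic, so identical input yields an
    identical module list.
    """
    params = params or McodeParams()
    if network.number_of_nodes() == 0:
        return []
    weights = vertex_weights(network, params.degree_cutoff)
    order = sorted(network.nodes(), key=lambda v: (-weights[v], v))
    visited: set[str] = set()
    modules: list[DetectedModule] = []

    for seed in order:
        if seed in visited:
            continue
        members = _grow(network, seed, weights, visited, params.node_score_cutoff, params.max_depth)
        visited |= members

        candidate = network.subgraph(members)
        if params.k_core_filter > 0 and not nx.k_core(candidate, params.k_core_filter):
            continue
        if params.haircut:
            members = _haircut(candidate)
            if len(members) < 2:
                continue
            candidate = network.subgraph(members)

        fluffed: set[str] = set()
        if params.fluff:
            boundary = {nb for m in members for nb in network.neighbors(m)} - set(members)
            for nb in sorted(boundary):
                closed = list(network.neighbors(nb)) + [nb]
                h = network.subgraph(closed)
                if _density(h.number_of_nodes(), h.number_of_edges()) > params.fluff_threshold:
                    fluffed.add(nb)

        n, e = candidate.number_of_nodes(), candidate.number_of_edges()
        modules.append(
            DetectedModule(
                members=frozenset(members),
                seed=seed,
                n_nodes=n,
                n_edges=e,
                score=score_from_counts(n, e),
                fluffed=frozenset(fluffed),
            )
        )

    modules.sort(key=lambda m: (-m.score, -m.n_nodes, m.seed))
    return modules


def score_from_counts(n_nodes: int, n_edges: int) -> float:
    """Module score = loop-free density × node count = 2E/(N−1)."""
    if n_nodes < 2:
        raise ValueError(f"module score needs >= 2 nodes, got {n_nodes}")
    return 2.0 * n_edges / (n_nodes - 1)


def module_score(network: nx.Graph, members: set[str] | frozenset[str]) -> float:
    """Score of the subgraph induced by ``members`` in ``network``."""
    members = set(members)
    missing = members - set(network.nodes())
    if missing:
        raise ValueError(f"members not in network: {sorted(missing)[:5]}")
    if len(members) < 2:
        raise ValueError("module score needs >= 2 members")
    sub = network.subgraph(members)
    return score_from_counts(sub.number_of_nodes(), sub.number_of_edges())


def module_table(modules: list[DetectedModule], decimals: int = 3):
    """Cluster report table (Cluster, Score, Nodes, Edges, Members)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cluster": i + 1,
                "score": round(m.score, decimals),
                "nodes": m.n_nodes,
                "edges": m.n_edges,
                "members": ", ".join(sorted(m.members)),
            }
            for i, m in enumerate(modules)
        ]
    )
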