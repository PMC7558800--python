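"""PPI network construction from STRING-style TSV exports, plus degree/hub tables.

The interaction file is the standard three-column export — two node columns
and a combined confidence score. Both common score dialects are accepted:
probabilities on [0, 1] and integer scores on [0, 999] (auto-detected by the
maximum value unless pinned). The network is an undirected simple graph:
reciprocal duplicates collapse (keeping the larger score), self-loops are
dropped, and every node carries a category label from the target-space
Venn partition. Hub analysis is by degree only — the number of interaction
partners — reported as a deterministic ranked table.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .targets import GeneSetBundle

logger = logging.getLogger(__name__)

__all__ = [
    "read_string_tsv",
    "build_network",
    "degree_table",
    "write_sif",
    "write_graphml",
    "write_edges_tsv",
]

Edge = tuple[str, str, float]

_DEFAULT_EDGE_COLUMNS = ("node1", "node2", "combined_score")


def read_string_tsv(
    source: str | Path | io.TextIOBase,
    score_min: float = 0.4,
    columns: Sequence[str] = _DEFAULT_EDGE_COLUMNS,
    scale: str = "auto",
) -> list[Edge]:
    """Parse a STRING-dialect TSV edge list into a deduplicated edge list.

    Parameters
    ----------
    source
        Path or open text stream with a one-line header naming the two node
        columns and the combined-score column (``columns``).
    score_min
        Confidence threshold on the 0–1 probability scale; 0.4 is the usual
        "medium confidence" cut. When the file uses the integer 0–999
        dialect the threshold is rescaled accordingly.
    scale
        ``"auto"`` (detect by maximum score), ``"unit"`` (0–1) or
        ``"integer"`` (0–999). Scores are stored as found in the file.

    Reciprocal duplicates (A–B and B–A) collapse to one edge keeping the
    maximum score; self-loops are dropped; symbols are uppercased.
    Malformed rows are logged and skipped. Zero surviving edges is an error.
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t")
    else:
        df = pd.read_csv(source, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"edge table lacks required columns {missing}; found {list(df.columns)}")
    c1, c2, cs = columns

    raw: list[Edge] = []
    n_bad = n_loops = 0
    for _, row in df.iterrows():
        try:
            a = str(row[c1]).strip().upper()
            b = str(row[c2]).strip().upper()
            s = float(row[cs])
        except (TypeError, ValueError):
            n_bad += 1
            continue
        if not a or not b or a == "NAN" or b == "NAN" or s != s:
            n_bad += 1
            continue
        if a == b:
            n_loops += 1
            continue
        raw.append((a, b, s))
    if n_bad:
        logger.warning("skipped %d malformed edge rows", n_bad)
    if n_loops:
        logger.info("dropped %d self-loops", n_loops)
    if not raw:
        raise ValueError("no valid edges parsed from input")

    max_score = max(s for _, _, s in raw)
    if scale == "auto":
        scale = "integer" if max_score > 1.0 else "unit"
    threshold = score_min * 999.0 if scale == "integer" else score_min

    best: dict[tuple[str, str], float] = {}
    for a, b, s in raw:
        if s < threshold:
            continue
        key = (a, b) if a < b else (b, a)
        if s > best.get(key, float("-inf")):
            best[key] = s
    if not best:
        raise ValueError(f"no edges survive score_min={score_min} ({scale} scale)")
    return [(a, b, s) for (a, b), s in sorted(best.items())]


def build_network(
    edges: Iterable[Edge],
    bundle: GeneSetBundle,
    restrict: bool = True,
) -> nx.Graph:
    """Assemble the categorized interaction network.

    With ``restrict=True`` (default) only edges whose both endpoints carry a
    category are kept; categorized symbols that end up with no surviving
    edge are retained as isolated degree-0 nodes, so the node set always
    equals the categorized gene space.
    """
    category = bundle.category_of()
    g = nx.Graph()
    for sym, cat in category.items():
        g.add_node(sym, category=cat)
    n_dropped = 0
    for a, b, s in edges:
        if restrict and (a not in category or b not in category):
            n_dropped += 1
            continue
        if a not in category:
            g.add_node(a, category="uncategorized")
        if b not in category:
            g.add_node(b, category="uncategorized")
        prev = g.get_edge_data(a, b)
        if prev is None or s > prev["score"]:
            g.add_edge(a, b, score=s)
    if n_dropped:
        logger.info("dropped %d edges with uncategorized endpoints", n_dropped)
    return g


def degree_table(
    network: nx.Graph,
    top_k: int | None = None,
    per_category: bool = False,
) -> pd.DataFrame:
    """Ranked degree table: degree descending, ties lexicographic by symbol.

    ``top_k`` slices the head overall, or per category when
    ``per_category=True`` (mirroring hub reports split into shared /
    drug-only / disease-only genes).
    """
    if top_k is not None and top_k <= 0:
        raise ValueError(f"top_k must be positive, got {top_k}")
    rows = [
        {"symbol": n, "degree": d, "category": network.nodes[n].get("category", "uncategorized")}
        for n, d in network.degree()
    ]
    df = pd.DataFrame(rows, columns=["symbol", "degree", "category"])
    df = df.sort_values(["degree", "symbol"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
    if top_k is None:
        return df
    if per_category:
        return (
            df.groupby("category", group_keys=False, sort=False)[df.columns]
            .head(top_k)
            .reset_index(drop=True)
        )
    return df.head(top_k).reset_index(drop=True)


def write_sif(network: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Write edges as SIF lines (``A pp B``); isolated nodes as bare names."""
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges()):
            fh.write(f"{a}\t{relation}\t{b}\n")
        for n in sorted(network.nodes()):
            if network.degree(n) == 0:
                fh.write(f"{n}\n")


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, path)


def write_edges_tsv(
    edges: Iterable[Edge],
    path_or_stream: str | Path | io.TextIOBase,
    columns: Sequence[str] = _DEFAULT_EDGE_COLUMNS,
) -> None:
    """Serialize an edge list back to the STRING TSV dialect."""
    df = pd.DataFrame(list(edges), columns=list(columns))
    df.to_csv(path_or_stream, sep="\t", index=False)
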