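"""Gene-set over-representation analysis against GMT annotation collections.

For a query gene set of effective size n drawn from a universe of N genes,
the overlap k with a term of size K is scored by the upper-tail
hypergeometric probability

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N−K, n−i) / C(N, n),

optionally in the conservative EASE variant (overlap reduced by one before
the tail, the default score of classic annotation servers). P-values are
Benjamini–Hochberg adjusted within one collection, and fold enrichment
(k/n)/(K/N) is reported for bubble-chart export. Result ranking follows the
convention of ascending p with larger overlap counts first among ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationCollection",
    "EnrichmentRecord",
    "enrich",
    "bh_adjust",
    "rank_enrichment",
    "read_gmt",
    "write_gmt",
    "enrichment_table",
    "bubble_table",
]


@dataclass
class AnnotationCollection:
    """Named annotation terms over a gene universe.

    ``universe`` defaults to the union of all term member sets (a proxy for
    a proprietary annotation background); pass an explicit universe to use
    e.g. all network genes instead.
    """

    name: str
    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} is empty")
        if not self.universe:
            self.universe = frozenset().union(*(g for _, g in self.terms.values())) if self.terms else frozenset()
        for tid, (_, genes) in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {tid!r} has members outside the universe")


@dataclass(frozen=True)
class EnrichmentRecord:
    term_id: str
    description: str
    k: int          # overlap count
    n: int          # effective query size (genes found in universe)
    K: int          # term size
    N: int          # universe size
    p: float
    p_ease: float
    fdr: float
    fold_enrichment: float


def _hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    # P[X >= k] for X ~ Hypergeom(N, K, n); sf(k-1) is the upper tail at k
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    arr = np.asarray(list(pvals), dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(arr, method="fdr_bh")
    return adj.tolist()


def enrich(
    query: Iterable[str],
    collection: AnnotationCollection,
    method: str = "hypergeometric",
    fdr_alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Test every term for over-representation of ``query``.

    Query genes outside the collection's universe are dropped (count
    logged). Only terms with overlap k >= 1 are reported. ``method`` is
    ``"hypergeometric"`` (textbook upper tail) or ``"ease"`` — either way
    both p and p_ease are stored; ``method`` selects which drives the FDR
    and the ranking. Raises if no query gene lies in the universe.
    """
    if method not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown method {method!r}")
    q = {s.strip().upper() for s in query}
    effective = q & collection.universe
    dropped = len(q) - len(effective)
    if dropped:
        logger.info("dropped %d query genes outside the %s universe", dropped, collection.name)
    if not effective:
        raise ValueError("no query genes found in the annotation universe")

    N = len(collection.universe)
    n = len(effective)
    prelim = []
    for tid, (desc, genes) in sorted(collection.terms.items()):
        k = len(effective & genes)
        if k < 1:
            continue
        K = len(genes)
        p = _hypergeom_tail(k, n, K, N)
        k_ease = max(k - 1, 0)
        p_ease = _hypergeom_tail(k_ease, n, K, N) if k_ease >= 1 else 1.0
        fe = (k / n) / (K / N)
        prelim.append((tid, desc, k, K, p, p_ease, fe))

    key = 4 if method == "hypergeometric" else 5
    fdrs = bh_adjust([row[key] for row in prelim])
    records = [
        EnrichmentRecord(
            term_id=tid, description=desc, k=k, n=n, K=K, N=N,
            p=p, p_ease=pe, fdr=fdr, fold_enrichment=fe,
        )
        for (tid, desc, k, K, p, pe, fe), fdr in zip(prelim, fdrs)
    ]
    return rank_enrichment(records, method=method)


def rank_enrichment(records: Sequence[EnrichmentRecord], by: str = "p_then_count", method: str = "hypergeometric") -> list[EnrichmentRecord]:
    """Order records by significance: ascending p, ties by overlap count
    descending, then term id."""
    if by != "p_then_count":
        raise ValueError(f"unknown ranking rule {by!r}")
    keyp = (lambda r: r.p) if method == "hypergeometric" else (lambda r: r.p_ease)
    return sorted(records, key=lambda r: (keyp(r), -r.k, r.term_id))


def read_gmt(path: str | Path, name: str | None = None, universe: Iterable[str] | None = None) -> AnnotationCollection:
    """Read a GMT file (term <tab> description <tab> gene...)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("skipping short GMT line: %r", line[:60])
                continue
            tid, desc, genes = parts[0], parts[1], parts[2:]
            terms[tid] = (desc, frozenset(g.strip().upper() for g in genes if g.strip()))
    return AnnotationCollection(
        name=name or Path(path).stem,
        terms=terms,
        universe=frozenset(s.strip().upper() for s in universe) if universe else frozenset(),
    )


def write_gmt(collection: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, (desc, genes) in sorted(collection.terms.items()):
            fh.write("\t".join([tid, desc, *sorted(genes)]) + "\n")


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id, "description": r.description,
                "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "p": r.p, "p_ease": r.p_ease, "fdr": r.fdr,
                "fold_enrichment": r.fold_enrichment,
            }
            for r in records
        ]
    )


def bubble_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Bubble-chart export: x = fold enrichment, point size = overlap count."""
    return pd.DataFrame(
        [
            {"term_id": r.term_id, "description": r.description, "fold_enrichment": r.fold_enrichment, "p": r.p, "k": r.k}
            for r in records
        ]
    )
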