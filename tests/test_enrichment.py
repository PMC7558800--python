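"""Over-representation statistics: hypergeometric tail, EASE, BH, ranking, GMT I/O."""

import itertools
import math
import random

import numpy as np
import pytest

from netpharm.enrichment import (
    AnnotationCollection,
    EnrichmentRecord,
    bh_adjust,
    enrich,
    rank_enrichment,
    read_gmt,
    write_gmt,
    bubble_table,
)


def collection(terms, universe=None):
    return AnnotationCollection(
        name="test",
        terms={tid: (f"desc {tid}", frozenset(genes)) for tid, genes in terms.items()},
        universe=frozenset(universe) if universe else frozenset(),
    )


def exhaustive_tail(k, n, K, N):
    """Oracle: enumerate every n-subset of the universe and count overlaps >= k."""
    universe = range(N)
    term = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(term & set(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_matches_exhaustive_enumeration(self):
        genes = [f"G{i}" for i in range(20)]
        coll = collection({"T": genes[:5]}, universe=genes)
        query = set(genes[:3] + genes[10:12])  # k=3 of K=5, n=5, N=20
        rec = enrich(query, coll)[0]
        assert (rec.k, rec.n, rec.K, rec.N) == (3, 5, 5, 20)
        assert rec.p == pytest.approx(exhaustive_tail(3, 5, 5, 20), rel=1e-12)

    def test_query_equals_universe_is_unenriched(self):
        genes = [f"G{i}" for i in range(8)]
        coll = collection({"T": genes}, universe=genes)
        rec = enrich(set(genes), coll)[0]
        assert rec.p == pytest.approx(1.0)
        assert rec.fold_enrichment == pytest.approx(1.0)

    def test_fold_enrichment_arithmetic(self):
        genes = [f"G{i}" for i in range(100)]
        coll = collection({"T": genes[:4]}, universe=genes)
        query = set(genes[:2] + genes[50:58])  # k=2, n=10, K=4, N=100
        rec = enrich(query, coll)[0]
        assert rec.fold_enrichment == pytest.approx(5.0)

    def test_ease_is_more_conservative(self):
        genes = [f"G{i}" for i in range(50)]
        coll = collection({"T": genes[:10]}, universe=genes)
        rec = enrich(set(genes[:6]), coll)[0]
        assert rec.p <= rec.p_ease

    def test_p_monotone_in_overlap(self):
        genes = [f"G{i}" for i in range(40)]
        coll = collection({"T": genes[:10]}, universe=genes)
        ps = []
        for k in range(1, 6):
            query = set(genes[:k]) | set(genes[20 : 20 + (8 - k)])
            ps.append(enrich(query, coll)[0].p)
        assert ps == sorted(ps, reverse=True)

    def test_outside_universe_genes_dropped_and_empty_query_errors(self):
        genes = [f"G{i}" for i in range(10)]
        coll = collection({"T": genes[:5]}, universe=genes)
        rec = enrich(set(genes[:3]) | {"ALIEN1"}, coll)[0]
        assert rec.n == 3
        with pytest.raises(ValueError):
            enrich({"ALIEN1", "ALIEN2"}, coll)

    def test_label_permutation_invariance(self):
        rng = random.Random(9)
        genes = [f"G{i}" for i in range(30)]
        term = rng.sample(genes, 8)
        query = set(rng.sample(genes, 10))
        p0 = enrich(query, collection({"T": term}, universe=genes))[0].p
        relabel = {g: f"X{i}" for i, g in enumerate(rng.sample(genes, len(genes)))}
        p1 = enrich(
            {relabel[g] for g in query},
            collection({"T": [relabel[g] for g in term]}, universe=[relabel[g] for g in genes]),
        )[0].p
        assert p0 == pytest.approx(p1, rel=1e-12)


class TestBH:
    def bh_oracle(self, ps):
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        adj = [0.0] * m
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            val = min(prev, ps[i] * m / rank)
            adj[i] = val
            prev = val
        return adj

    def test_single_and_equal_values(self):
        assert bh_adjust([0.01]) == [pytest.approx(0.01)]
        assert bh_adjust([0.05, 0.05, 0.05]) == pytest.approx([0.05, 0.05, 0.05])

    def test_matches_textbook_stepup_on_uniforms(self):
        rng = np.random.default_rng(12)
        ps = rng.uniform(0, 1, size=50).tolist()
        assert bh_adjust(ps) == pytest.approx(self.bh_oracle(ps), rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestRanking:
    def rec(self, tid, p, k):
        return EnrichmentRecord(tid, "", k, 10, 5, 100, p, p, p, 1.0)

    def test_p_ascending_then_count_descending(self):
        recs = [self.rec("A", 0.02, 3), self.rec("B", 0.01, 3), self.rec("C", 0.01, 12)]
        assert [r.term_id for r in rank_enrichment(recs)] == ["C", "B", "A"]

    def test_matches_two_key_sort_oracle(self):
        rng = random.Random(2)
        recs = [self.rec(f"T{i}", rng.choice([0.01, 0.02, 0.05]), rng.randrange(1, 20)) for i in range(40)]
        got = [r.term_id for r in rank_enrichment(recs)]
        expect = [r.term_id for r in sorted(recs, key=lambda r: (r.p, -r.k, r.term_id))]
        assert got == expect


class TestGmtIO:
    def test_round_trip(self, tmp_path):
        coll = collection({"T1": ["A", "B", "C"], "T2": ["B", "D"]})
        p = tmp_path / "c.gmt"
        write_gmt(coll, p)
        back = read_gmt(p)
        assert back.terms == coll.terms
        assert back.universe == coll.universe

    def test_empty_term_rejected(self):
        with pytest.raises(ValueError):
            collection({"T": []})

    def test_term_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            collection({"T": ["A", "B"]}, universe=["A"])


def test_bubble_export_mirrors_fold_enrichment():
    genes = [f"G{i}" for i in range(30)]
    coll = collection({"T1": genes[:5], "T2": genes[5:15]}, universe=genes)
    recs = enrich(set(genes[:8]), coll)
    df = bubble_table(recs)
    assert list(df["fold_enrichment"]) == [r.fold_enrichment for r in recs]
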