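"""Target-space assembly: per-herb target sets, disease genes, and the Venn split.

Compound-to-target mappings (pharmacophore predictions resolved to official
gene symbols) are aggregated into per-herb target sets and their union;
disease genes pass a relevance-score filter (strictly greater than the
threshold, default 2.5). Every network node is then classified as

* ``shared``       — drug target and disease gene,
* ``drug_only``    — drug target not associated with the disease,
* ``disease_only`` — disease gene not hit by any screened compound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TargetMappingRecord",
    "DiseaseGeneRecord",
    "GeneSetBundle",
    "assemble_target_sets",
    "filter_disease_genes",
    "classify_nodes",
    "read_mapping_table",
    "read_disease_table",
    "write_venn_counts",
]

DEFAULT_SPECIES = "Homo sapiens"


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class TargetMappingRecord:
    compound_id: str
    protein_id: str
    gene_symbol: str
    species: str = DEFAULT_SPECIES

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_symbol", _norm(self.gene_symbol))
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")


@dataclass(frozen=True)
class DiseaseGeneRecord:
    gene_symbol: str
    relevance: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_symbol", _norm(self.gene_symbol))
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be non-empty")
        if self.relevance < 0:
            raise ValueError(f"relevance must be >= 0, got {self.relevance}")


@dataclass
class GeneSetBundle:
    """Named gene sets: per-herb targets, their union, disease genes, and the
    shared / drug-only / disease-only partition of the Venn diagram."""

    per_herb: dict[str, frozenset[str]] = field(default_factory=dict)
    drug_union: frozenset[str] = frozenset()
    disease: frozenset[str] = frozenset()
    shared: frozenset[str] = frozenset()
    drug_only: frozenset[str] = frozenset()
    disease_only: frozenset[str] = frozenset()

    def category_of(self) -> dict[str, str]:
        """Map every categorized symbol to its category label."""
        out: dict[str, str] = {}
        for cat, syms in (("shared", self.shared), ("drug_only", self.drug_only), ("disease_only", self.disease_only)):
            for s in syms:
                out[s] = cat
        return out

    @property
    def venn_counts(self) -> dict[str, int]:
        return {
            "shared": len(self.shared),
            "drug_only": len(self.drug_only),
            "disease_only": len(self.disease_only),
        }


def assemble_target_sets(
    mappings: Sequence[TargetMappingRecord],
    screened_compounds: set[str],
    herb_of: Mapping[str, Iterable[str]],
    species: str = DEFAULT_SPECIES,
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """Aggregate mapping rows into per-herb target sets and their union.

    Rows whose compound is not in the screened candidate set, or whose
    species tag differs from the configured one, are dropped with a log
    entry. Symbols are normalized to stripped uppercase. Raises if the
    mapping table is empty.
    """
    if not mappings:
        raise ValueError("assemble_target_sets: empty mapping table")
    per_herb: dict[str, set[str]] = {}
    dropped_unknown = dropped_species = 0
    for m in mappings:
        if m.species != species:
            dropped_species += 1
            continue
        if m.compound_id not in screened_compounds:
            dropped_unknown += 1
            continue
        for herb in herb_of.get(m.compound_id, ()):
            per_herb.setdefault(herb, set()).add(m.gene_symbol)
    if dropped_unknown:
        logger.info("dropped %d mapping rows for unscreened compounds", dropped_unknown)
    if dropped_species:
        logger.info("dropped %d mapping rows with species != %r", dropped_species, species)
    frozen = {h: frozenset(s) for h, s in sorted(per_herb.items())}
    union = frozenset().union(*frozen.values()) if frozen else frozenset()
    return frozen, union


def filter_disease_genes(
    records: Sequence[DiseaseGeneRecord],
    min_relevance: float = 2.5,
) -> frozenset[str]:
    """Keep disease genes with relevance strictly greater than ``min_relevance``.

    Duplicate symbols are collapsed keeping the maximum relevance (database
    exports repeat symbols across entries).
    """
    best: dict[str, float] = {}
    for r in records:
        best[r.gene_symbol] = max(best.get(r.gene_symbol, float("-inf")), r.relevance)
    return frozenset(s for s, rel in best.items() if rel > min_relevance)


def classify_nodes(drug_union: Iterable[str], disease: Iterable[str]) -> GeneSetBundle:
    """Split symbols into shared / drug-only / disease-only (the Venn partition)."""
    d = frozenset(_norm(s) for s in drug_union)
    z = frozenset(_norm(s) for s in disease)
    return GeneSetBundle(
        drug_union=d,
        disease=z,
        shared=d & z,
        drug_only=d - z,
        disease_only=z - d,
    )


def build_bundle(
    per_herb: dict[str, frozenset[str]],
    drug_union: frozenset[str],
    disease: frozenset[str],
) -> GeneSetBundle:
    bundle = classify_nodes(drug_union, disease)
    bundle.per_herb = dict(per_herb)
    return bundle


def read_mapping_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[TargetMappingRecord]:
    """Read a compound → protein → gene-symbol mapping table."""
    cols = {"compound_id": "compound_id", "protein_id": "protein_id", "gene_symbol": "gene_symbol", "species": "species"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep, engine="python")
    has_species = cols["species"] in df.columns
    return [
        TargetMappingRecord(
            compound_id=str(row[cols["compound_id"]]).strip(),
            protein_id=str(row.get(cols["protein_id"], "")).strip(),
            gene_symbol=str(row[cols["gene_symbol"]]),
            species=str(row[cols["species"]]).strip() if has_species else DEFAULT_SPECIES,
        )
        for _, row in df.iterrows()
    ]


def read_disease_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> list[DiseaseGeneRecord]:
    """Read a two-column (symbol, relevance) disease-gene table."""
    cols = {"gene_symbol": "gene_symbol", "relevance": "relevance"}
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep, engine="python")
    return [
        DiseaseGeneRecord(gene_symbol=str(row[cols["gene_symbol"]]), relevance=float(row[cols["relevance"]]))
        for _, row in df.iterrows()
    ]


def write_venn_counts(bundle: GeneSetBundle, path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"category": "shared", "count": len(bundle.shared)},
            {"category": "drug_only", "count": len(bundle.drug_only)},
            {"category": "disease_only", "count": len(bundle.disease_only)},
            {"category": "drug_union", "count": len(bundle.drug_union)},
            {"category": "disease", "count": len(bundle.disease)},
        ]
    )
    df.to_csv(path, index=False)
    return df
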