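"""Synthetic study generator: desk-scale stand-ins for the web databases.

Every pipeline stage consumes a file dialect normally exported from an
online resource (compound property tables, target mappings, disease-gene
relevance lists, interaction TSVs, GMT annotation catalogues). This module
fabricates all of them with the statistical structure each stage assumes:

* compound properties straddle the screening thresholds so the pass rule is
  actually exercised near its boundaries;
* the interactome is a planted-partition graph — dense blocks (within-block
  edge probability ``p_in``) on a sparse background (``p_out``), the
  structure density-based module detection looks for;
* annotation collections contain one designated term deliberately
  over-represented in the first planted block.

Ground-truth labels always accompany generated data and are never read by
any analysis stage. All randomness flows from one seeded generator, so the
same seed reproduces byte-identical outputs.

The planted-partition model is intentionally simple (no degree correction,
no literature bias); see the methods note for what that does and does not
validate about real interactomes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compounds import CompoundRecord
from .enrichment import AnnotationCollection
from .network import write_edges_tsv
from .targets import DiseaseGeneRecord, TargetMappingRecord

__all__ = [
    "SynthSpec",
    "synth_compound_table",
    "synth_ppi",
    "synth_annotations",
    "synth_mapping_table",
    "synth_disease_table",
    "generate_study",
]

HERBS = ("HQ", "CX", "DL", "JC")


@dataclass(frozen=True)
class SynthSpec:
    """Shape of one synthetic study.

    Defaults define the standard benchmark conditions: a 200-gene
    background interactome with one planted 20-node module at within-module
    edge probability 0.6 over a 0.02 background, 100 candidate compounds
    half of which pass the screen, and 50 annotation terms of which one
    shares 15 genes with the planted module.
    """

    seed: int = 0
    n_compounds: int = 100
    frac_pass: float = 0.5
    n_background: int = 200
    module_sizes: tuple[int, ...] = (20,)
    p_in: float = 0.6
    p_out: float = 0.02
    n_terms: int = 50
    enriched_term_overlap: int = 15
    term_size_range: tuple[int, int] = (10, 40)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError(f"need 0 <= p_out < p_in <= 1, got p_out={self.p_out}, p_in={self.p_in}")
        if any(s < 3 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 3")
        if sum(self.module_sizes) > self.n_background:
            raise ValueError("planted modules exceed the background size")
        if not (0.0 <= self.frac_pass <= 1.0):
            raise ValueError("frac_pass must lie in [0, 1]")
        if self.module_sizes and self.enriched_term_overlap > self.module_sizes[0]:
            raise ValueError("enriched_term_overlap larger than the first planted module")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _gene_names(n: int) -> list[str]:
    return [f"GEN{i:04d}" for i in range(n)]


def synth_compound_table(spec: SynthSpec) -> tuple[list[CompoundRecord], pd.DataFrame]:
    """Candidate compounds with properties straddling the screen bounds.

    Each compound is drawn to pass all three criteria with probability
    ``frac_pass``; failing compounds violate a random non-empty subset of
    criteria, with values sampled just outside the bound. Returns the
    records plus a truth table with the intended status.
    """
    rng = spec.rng(1)
    records: list[CompoundRecord] = []
    truth_rows = []
    for i in range(spec.n_compounds):
        cid = f"CMP{i:04d}"
        herbs = frozenset(rng.choice(HERBS, size=rng.integers(1, 3), replace=False).tolist())
        intended_pass = bool(rng.random() < spec.frac_pass)
        # passing-side values sit just above each bound; failing compounds
        # push a random subset of properties just below it
        ob = float(rng.uniform(30.0, 45.0))
        caco2 = float(rng.uniform(-0.39, 0.6))
        dl = float(rng.uniform(0.18, 0.5))
        if not intended_pass:
            fail_mask = rng.random(3) < 0.5
            if not fail_mask.any():
                fail_mask[rng.integers(0, 3)] = True
            if fail_mask[0]:
                ob = float(rng.uniform(5.0, 29.99))
            if fail_mask[1]:
                caco2 = float(rng.uniform(-1.2, -0.4))  # upper end hits the strict bound exactly
            if fail_mask[2]:
                dl = float(rng.uniform(0.0, 0.1799))
        records.append(CompoundRecord(cid, f"compound-{i}", herbs, ob=ob, caco2=caco2, dl=dl))
        truth_rows.append({"compound_id": cid, "intended_status": "pass" if intended_pass else "fail"})
    return records, pd.DataFrame(truth_rows)


def synth_ppi(spec: SynthSpec) -> tuple[str, pd.DataFrame]:
    """Planted-partition interactome emitted in the STRING TSV dialect.

    Within-block gene pairs are edged with probability ``p_in``, all other
    pairs with ``p_out``. Confidence scores are uniform on [0.4, 0.999] so
    the default reader threshold keeps every emitted edge. Returns the TSV
    text and a truth table mapping each gene to its planted block (−1 for
    background).
    """
    rng = spec.rng(2)
    genes = _gene_names(spec.n_background)
    block = np.full(spec.n_background, -1, dtype=int)
    start = 0
    for b, size in enumerate(spec.module_sizes):
        block[start : start + size] = b
        start += size

    n = spec.n_background
    iu, ju = np.triu_indices(n, k=1)
    same = (block[iu] == block[ju]) & (block[iu] >= 0)
    prob = np.where(same, spec.p_in, spec.p_out)
    keep = rng.random(len(iu)) < prob
    scores = rng.uniform(0.4, 0.999, size=int(keep.sum())).round(3)
    edges = [
        (genes[a], genes[b], float(s))
        for a, b, s in zip(iu[keep], ju[keep], scores)
    ]
    buf = io.StringIO()
    write_edges_tsv(edges, buf)
    truth = pd.DataFrame({"gene_symbol": genes, "planted_module": block})
    return buf.getvalue(), truth


def synth_annotations(
    spec: SynthSpec,
    planted_module_members: set[str] | frozenset[str],
) -> tuple[AnnotationCollection, pd.DataFrame]:
    """Annotation terms over the gene universe, one planted enriched term.

    ``n_terms`` random term sets are drawn over the background universe; a
    designated term ``T_PLANTED`` shares ``enriched_term_overlap`` members
    with the planted module, the rest of its members drawn outside it.
    """
    planted = sorted(planted_module_members)
    if not planted:
        raise ValueError("planted module members must be non-empty")
    if spec.enriched_term_overlap > len(planted):
        raise ValueError("enriched_term_overlap exceeds the planted module size")
    rng = spec.rng(3)
    universe = _gene_names(spec.n_background)
    lo, hi = spec.term_size_range
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for t in range(spec.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        terms[f"T{t:04d}"] = (f"random term {t}", frozenset(members.tolist()))

    overlap = rng.choice(planted, size=spec.enriched_term_overlap, replace=False).tolist()
    outside = sorted(set(universe) - set(planted))
    n_fill = max(int(rng.integers(lo, hi + 1)) - len(overlap), 0)
    fill = rng.choice(outside, size=min(n_fill, len(outside)), replace=False).tolist()
    terms["T_PLANTED"] = ("planted enriched term", frozenset(overlap + fill))

    collection = AnnotationCollection(name="synthetic", terms=terms, universe=frozenset(universe))
    truth = pd.DataFrame({"term_id": ["T_PLANTED"], "overlap_with_planted": [spec.enriched_term_overlap]})
    return collection, truth


def synth_mapping_table(
    spec: SynthSpec,
    compounds: list[CompoundRecord],
    drug_genes: list[str],
) -> list[TargetMappingRecord]:
    """Compound → target mappings covering every drug gene at least once."""
    rng = spec.rng(4)
    if not compounds:
        raise ValueError("need at least one compound")
    rows: list[TargetMappingRecord] = []
    cids = [c.compound_id for c in compounds]
    for g in drug_genes:
        hits = rng.choice(cids, size=int(rng.integers(1, min(4, len(cids)) + 1)), replace=False)
        for cid in hits:
            rows.append(TargetMappingRecord(cid, f"P{rng.integers(0, 10**4):04d}", g))
    return rows


def synth_disease_table(
    spec: SynthSpec,
    disease_genes: list[str],
    n_decoys: int = 30,
) -> list[DiseaseGeneRecord]:
    """Disease genes above the relevance cut plus sub-threshold decoys."""
    rng = spec.rng(5)
    rows = [DiseaseGeneRecord(g, float(rng.uniform(2.6, 12.0))) for g in disease_genes]
    rows += [DiseaseGeneRecord(f"DECOY{i:03d}", float(rng.uniform(0.0, 2.5))) for i in range(n_decoys)]
    return rows


@dataclass
class SyntheticStudy:
    """All generated inputs for one end-to-end run, plus ground truth."""

    compounds: list[CompoundRecord]
    mapping: list[TargetMappingRecord]
    disease: list[DiseaseGeneRecord]
    ppi_tsv: str
    annotations: AnnotationCollection
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def planted_members(self) -> frozenset[str]:
        t = self.truth["ppi"]
        return frozenset(t.loc[t.planted_module == 0, "gene_symbol"])


def generate_study(spec: SynthSpec) -> SyntheticStudy:
    """Generate one coherent synthetic study.

    Every background gene is assigned to the drug-target list, the disease
    list, or both, so the categorized gene space covers the whole
    interactome and the restricted network keeps the planted structure.
    """
    compounds, compound_truth = synth_compound_table(spec)
    ppi_tsv, ppi_truth = synth_ppi(spec)
    genes = ppi_truth["gene_symbol"].tolist()

    rng = spec.rng(6)
    drug_genes, disease_genes = [], []
    for g in genes:
        r = rng.random()
        if r < 1 / 3:
            drug_genes.append(g)
        elif r < 2 / 3:
            disease_genes.append(g)
        else:
            drug_genes.append(g)
            disease_genes.append(g)

    passing = [c for c in compounds if (c.ob or 0) >= 30 and (c.caco2 or -1) > -0.4 and (c.dl or 0) >= 0.18]
    if not passing:  # degenerate frac_pass=0: map through all candidates
        passing = compounds
    mapping = synth_mapping_table(spec, passing, drug_genes)
    disease = synth_disease_table(spec, disease_genes)
    planted = frozenset(ppi_truth.loc[ppi_truth.planted_module == 0, "gene_symbol"]) if spec.module_sizes else frozenset(genes[:3])
    annotations, ann_truth = synth_annotations(spec, planted)

    return SyntheticStudy(
        compounds=compounds,
        mapping=mapping,
        disease=disease,
        ppi_tsv=ppi_tsv,
        annotations=annotations,
        truth={"compounds": compound_truth, "ppi": ppi_truth, "annotations": ann_truth},
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Emit the study as the exact file dialects the pipeline consumes."""
    from .compounds import ScreenResult, write_screen_table  # noqa: F401  (shared writer path)
    from .enrichment import write_gmt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = [
        {
            "compound_id": c.compound_id, "name": c.name, "herbs": "|".join(sorted(c.herbs)),
            "ob": c.ob, "caco2": c.caco2, "dl": c.dl, "whitelist": c.whitelist,
        }
        for c in study.compounds
    ]
    paths["compounds"] = out / "compounds.csv"
    pd.DataFrame(rows).to_csv(paths["compounds"], index=False)

    paths["mapping"] = out / "target_mapping.csv"
    pd.DataFrame(
        [
            {"compound_id": m.compound_id, "protein_id": m.protein_id, "gene_symbol": m.gene_symbol, "species": m.species}
            for m in study.mapping
        ]
    ).to_csv(paths["mapping"], index=False)

    paths["disease"] = out / "disease_genes.csv"
    pd.DataFrame(
        [{"gene_symbol": d.gene_symbol, "relevance": d.relevance} for d in study.disease]
    ).to_csv(paths["disease"], index=False)

    paths["ppi"] = out / "ppi_edges.tsv"
    paths["ppi"].write_text(study.ppi_tsv)

    paths["gmt"] = out / "annotations.gmt"
    write_gmt(study.annotations, paths["gmt"])

    for name, df in study.truth.items():
        p = out / f"truth_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"truth_{name}"] = p
    return paths
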