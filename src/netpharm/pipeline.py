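"""End-to-end orchestration of the five analysis stages.

``run_pipeline`` executes screen → target space → network → module
detection → enrichment from a single config, writing every report table
the analysis produces (screened compounds, Venn counts, degree table,
module table, enrichment and bubble tables) plus a machine-readable run
manifest capturing the config, input digests, package version and the
per-stage cardinalities. Identical config and inputs reproduce
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .compounds import ScreenCriteria, read_compound_table, screen_compounds, write_screen_table
from .enrichment import bubble_table, enrich, enrichment_table, read_gmt
from .mcode import McodeParams, find_modules, module_table
from .network import build_network, degree_table, read_string_tsv, write_sif
from .targets import (
    assemble_target_sets,
    build_bundle,
    filter_disease_genes,
    read_disease_table,
    read_mapping_table,
    write_venn_counts,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """Stage-named hard failure; aborts the run with a non-zero status."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of one run. Defaults reproduce the standard thresholds:
    OB >= 30, Caco-2 > -0.4, DL >= 0.18, disease relevance > 2.5,
    interaction confidence >= 0.4, plugin-default module detection."""

    compounds_path: str = "compounds.csv"
    mapping_path: str = "target_mapping.csv"
    disease_path: str = "disease_genes.csv"
    ppi_path: str = "ppi_edges.tsv"
    gmt_path: str = "annotations.gmt"
    outdir: str = "results"

    criteria: ScreenCriteria = field(default_factory=ScreenCriteria)
    min_relevance: float = 2.5
    score_min: float = 0.4
    score_scale: str = "auto"
    restrict_network: bool = True
    mcode: McodeParams = field(default_factory=McodeParams)
    enrich_method: str = "hypergeometric"
    fdr_alpha: float = 0.05
    enrich_top_module: bool = True
    top_k_degree: int = 20
    seed: int = 0

    compound_columns: dict[str, str] = field(default_factory=dict)
    mapping_columns: dict[str, str] = field(default_factory=dict)
    disease_columns: dict[str, str] = field(default_factory=dict)
    edge_columns: tuple[str, str, str] = ("node1", "node2", "combined_score")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        crit = ScreenCriteria(**raw.pop("criteria", {}))
        mc = McodeParams(**raw.pop("mcode", {}))
        if "edge_columns" in raw:
            raw["edge_columns"] = tuple(raw["edge_columns"])
        return cls(criteria=crit, mcode=mc, **raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["edge_columns"] = list(self.edge_columns)
        return d


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run all five stages; returns the manifest dict (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
    }
    for key in ("compounds_path", "mapping_path", "disease_path", "ppi_path", "gmt_path"):
        p = getattr(config, key)
        if not Path(p).exists():
            raise PipelineError("config", f"input file missing: {p}")
        manifest["inputs"][key] = {"path": str(p), "sha256": _digest(p)}

    # --- stage 1: compound screen ---
    try:
        records = read_compound_table(config.compounds_path, columns=config.compound_columns or None)
        screen = screen_compounds(records, config.criteria)
    except (ValueError, KeyError) as e:
        raise PipelineError("compound_screen", str(e)) from e
    write_screen_table(screen, out / "screened_compounds.csv")
    manifest["stages"]["compound_screen"] = {
        "n_input": len(records),
        "n_passed": len(screen.passed),
        "n_whitelisted": len(screen.whitelisted),
        "n_rejected": len(screen.rejected),
    }
    logger.info("compound_screen: %s", manifest["stages"]["compound_screen"])

    # --- stage 2: target space ---
    try:
        mappings = read_mapping_table(config.mapping_path, columns=config.mapping_columns or None)
        disease_records = read_disease_table(config.disease_path, columns=config.disease_columns or None)
        if not disease_records:
            raise ValueError("disease-gene table is empty")
        candidate_ids = {c.compound_id for c in screen.candidates}
        herb_of = {c.compound_id: sorted(c.herbs) for c in screen.candidates}
        per_herb, drug_union = assemble_target_sets(mappings, candidate_ids, herb_of)
        disease = filter_disease_genes(disease_records, config.min_relevance)
        bundle = build_bundle(per_herb, drug_union, disease)
    except (ValueError, KeyError) as e:
        raise PipelineError("target_space", str(e)) from e
    write_venn_counts(bundle, out / "venn_counts.csv")
    manifest["stages"]["target_space"] = {
        "n_mapping_rows": len(mappings),
        "n_drug_union": len(bundle.drug_union),
        "n_disease": len(bundle.disease),
        **bundle.venn_counts,
    }
    logger.info("target_space: %s", manifest["stages"]["target_space"])

    # --- stage 3: network construction ---
    try:
        edges = read_string_tsv(
            config.ppi_path, score_min=config.score_min,
            columns=config.edge_columns, scale=config.score_scale,
        )
        network = build_network(edges, bundle, restrict=config.restrict_network)
    except (ValueError, KeyError) as e:
        raise PipelineError("network_core", str(e)) from e
    deg = degree_table(network)
    deg.to_csv(out / "degree_table.csv", index=False)
    degree_table(network, top_k=config.top_k_degree, per_category=True).to_csv(
        out / "degree_top_per_category.csv", index=False
    )
    write_sif(network, out / "network.sif")
    manifest["stages"]["network_core"] = {
        "n_edges_read": len(edges),
        "n_nodes": network.number_of_nodes(),
        "n_edges": network.number_of_edges(),
    }
    logger.info("network_core: %s", manifest["stages"]["network_core"])

    # --- stage 4: module detection ---
    try:
        modules = find_modules(network, config.mcode)
    except ValueError as e:
        raise PipelineError("mcode", str(e)) from e
    mtable = module_table(modules)
    mtable.to_csv(out / "modules.csv", index=False)
    manifest["stages"]["mcode"] = {
        "n_modules": len(modules),
        "top_score": round(modules[0].score, 3) if modules else None,
    }
    logger.info("mcode: %s", manifest["stages"]["mcode"])

    # --- stage 5: enrichment ---
    try:
        collection = read_gmt(config.gmt_path)
        query = set(modules[0].members) if (config.enrich_top_module and modules) else set(network.nodes())
        records_e = enrich(query, collection, method=config.enrich_method, fdr_alpha=config.fdr_alpha)
    except (ValueError, KeyError) as e:
        raise PipelineError("enrichment", str(e)) from e
    enrichment_table(records_e).to_csv(out / "enrichment.csv", index=False)
    bubble_table(records_e).to_csv(out / "bubble_data.csv", index=False)
    manifest["stages"]["enrichment"] = {
        "n_terms_tested": len(records_e),
        "top_term": records_e[0].term_id if records_e else None,
    }
    logger.info("enrichment: %s", manifest["stages"]["enrichment"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
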