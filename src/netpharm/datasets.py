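"""Bundled example datasets.

Two small tables from a published four-herb stroke-formula study ship with
the package:

* ``load_candidate_compounds`` — the 42-row candidate compound table
  (32 screen-passing compounds plus 10 literature-whitelisted additions).
  The pass/whitelist status is as published; the OB / Caco-2 / DL property
  values are synthetic, generated to be consistent with each row's status,
  because the study reports status only.
* ``load_module_table`` — the 18-cluster module report (score, node and
  edge counts, member gene symbols) from the study's interaction-network
  analysis, used to verify the module-score arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .compounds import CompoundRecord, read_compound_table

__all__ = ["load_candidate_compounds", "load_module_table", "module_members"]


def _data_path(name: str):
    return resources.files("netpharm.data") / name


def load_candidate_compounds() -> list[CompoundRecord]:
    """The 42-row candidate table (synthetic property values, published status)."""
    with resources.as_file(_data_path("candidate_compounds.csv")) as p:
        return read_compound_table(p)


def load_module_table() -> pd.DataFrame:
    """The published 18-cluster module table (cluster, score, nodes, edges, members)."""
    with resources.as_file(_data_path("ppi_modules.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def module_members(table: pd.DataFrame, cluster: int) -> list[str]:
    """Parse one cluster's comma-joined member list into gene symbols."""
    row = table.loc[table["cluster"] == cluster]
    if row.empty:
        raise KeyError(f"no cluster {cluster} in table")
    return [s.strip() for s in row.iloc[0]["members"].split(",") if s.strip()]
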