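"""ADME screening of candidate herbal compounds.

Candidate molecules collected from compound databases are filtered on three
absorption/drug-likeness properties before target prediction:

* oral bioavailability (OB, percent) — fraction of an oral dose reaching
  systemic circulation,
* Caco-2 permeability (log-scale, dimensionless) — predicted intestinal
  permeability from Caco-2 cell-line models,
* drug-likeness (DL, dimensionless in [0, 1]) — similarity to known drugs.

The standard screen keeps compounds with OB >= 30 %, Caco-2 > -0.4 and
DL >= 0.18 (note the Caco-2 bound is strict; the other two are inclusive).
Compounds added from the literature despite failing the screen are carried
through on a whitelist flag and reported with their provenance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "ScreenCriteria",
    "ScreenResult",
    "screen_compounds",
    "read_compound_table",
    "write_screen_table",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One candidate molecule with its ADME properties.

    ``ob``, ``caco2`` and ``dl`` may be ``None`` when the source table does
    not report them; a non-whitelist record with a missing property is
    rejected with an explicit reason, never passed silently.
    """

    compound_id: str
    name: str
    herbs: frozenset[str]
    ob: float | None = None
    caco2: float | None = None
    dl: float | None = None
    whitelist: bool = False

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if not self.herbs:
            raise ValueError(f"{self.compound_id}: herb membership must be non-empty")
        if self.ob is not None and (math.isnan(self.ob) or self.ob < 0):
            raise ValueError(f"{self.compound_id}: OB must be >= 0, got {self.ob}")
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise ValueError(f"{self.compound_id}: DL must lie in [0, 1], got {self.dl}")


@dataclass(frozen=True)
class ScreenCriteria:
    """Screen thresholds: OB >= ob_min, Caco-2 > caco2_min (strict), DL >= dl_min."""

    ob_min: float = 30.0
    caco2_min: float = -0.4
    dl_min: float = 0.18

    def __post_init__(self) -> None:
        for name, v in (("ob_min", self.ob_min), ("caco2_min", self.caco2_min), ("dl_min", self.dl_min)):
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")


@dataclass
class ScreenResult:
    """Three-way partition of the candidate table.

    ``candidates`` (passed + whitelisted) is the compound set carried into
    target prediction. ``reasons`` maps rejected/whitelisted compound ids to
    machine-readable reason codes.
    """

    passed: list[CompoundRecord]
    whitelisted: list[CompoundRecord]
    rejected: list[CompoundRecord]
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def candidates(self) -> list[CompoundRecord]:
        return self.passed + self.whitelisted


def _failure_codes(rec: CompoundRecord, c: ScreenCriteria) -> list[str]:
    codes: list[str] = []
    for prop, value, bound, strict in (
        ("ob", rec.ob, c.ob_min, False),
        ("caco2", rec.caco2, c.caco2_min, True),
        ("dl", rec.dl, c.dl_min, False),
    ):
        if value is None or math.isnan(value):
            codes.append(f"missing:{prop}")
        elif strict and not value > bound:
            codes.append(f"{prop}<={bound}")
        elif not strict and not value >= bound:
            codes.append(f"{prop}<{bound}")
    return codes


def screen_compounds(
    records: Sequence[CompoundRecord],
    criteria: ScreenCriteria | None = None,
) -> ScreenResult:
    """Partition candidates into passed / whitelisted / rejected.

    Whitelisted records bypass the property screen entirely (they were added
    from the literature); every other record must satisfy all three bounds.
    The three output lists always partition the input.
    """
    if not records:
        raise ValueError("screen_compounds requires a non-empty record list")
    criteria = criteria or ScreenCriteria()
    seen: set[str] = set()
    result = ScreenResult([], [], [])
    for rec in records:
        if rec.compound_id in seen:
            raise ValueError(f"duplicate compound_id {rec.compound_id!r}")
        seen.add(rec.compound_id)
        if rec.whitelist:
            result.whitelisted.append(rec)
            result.reasons[rec.compound_id] = "whitelist"
            continue
        codes = _failure_codes(rec, criteria)
        if codes:
            result.rejected.append(rec)
            result.reasons[rec.compound_id] = ";".join(codes)
            logger.debug("rejected %s: %s", rec.compound_id, result.reasons[rec.compound_id])
        else:
            result.passed.append(rec)
    return result


_DEFAULT_COLUMNS = {
    "compound_id": "compound_id",
    "name": "name",
    "herbs": "herbs",
    "ob": "ob",
    "caco2": "caco2",
    "dl": "dl",
    "whitelist": "whitelist",
}

_TRUTHY = {"true", "1", "yes", "y", "t"}


def read_compound_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    herb_sep: str = "|",
    sep: str | None = None,
) -> list[CompoundRecord]:
    """Read a delimited candidate-compound table with a one-line header.

    Delimiter is sniffed (comma or tab) unless ``sep`` is given; source
    column names can be remapped via ``columns`` (keys are the canonical
    field names, values the names found in the file).
    """
    cols = dict(_DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=sep, engine="python")
    records: list[CompoundRecord] = []
    for _, row in df.iterrows():
        def prop(key: str) -> float | None:
            v = row.get(cols[key])
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

        wl = str(row.get(cols["whitelist"], "false")).strip().lower() in _TRUTHY
        records.append(
            CompoundRecord(
                compound_id=str(row[cols["compound_id"]]).strip(),
                name=str(row.get(cols["name"], "")).strip(),
                herbs=frozenset(h.strip() for h in str(row[cols["herbs"]]).split(herb_sep) if h.strip()),
                ob=prop("ob"),
                caco2=prop("caco2"),
                dl=prop("dl"),
                whitelist=wl,
            )
        )
    return records


def write_screen_table(result: ScreenResult, path: str | Path, herb_sep: str = "|") -> pd.DataFrame:
    """Emit the screen partition as one table with status and reason columns."""
    rows = []
    for status, recs in (("passed", result.passed), ("whitelisted", result.whitelisted), ("rejected", result.rejected)):
        for r in recs:
            rows.append(
                {
                    "compound_id": r.compound_id,
                    "name": r.name,
                    "herbs": herb_sep.join(sorted(r.herbs)),
                    "ob": r.ob,
                    "caco2": r.caco2,
                    "dl": r.dl,
                    "whitelist": r.whitelist,
                    "status": status,
                    "reason": result.reasons.get(r.compound_id, ""),
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def records_from_rows(rows: Iterable[dict]) -> list[CompoundRecord]:
    """Build records from dicts (convenience for generated tables)."""
    return [
        CompoundRecord(
            compound_id=r["compound_id"],
            name=r.get("name", r["compound_id"]),
            herbs=frozenset(r["herbs"]) if not isinstance(r["herbs"], str) else frozenset(r["herbs"].split("|")),
            ob=r.get("ob"),
            caco2=r.get("caco2"),
            dl=r.get("dl"),
            whitelist=bool(r.get("whitelist", False)),
        )
        for r in rows
    ]
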