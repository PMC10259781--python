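"""Four-table spontaneous-report schema and the relational join into cases.

A JADER-style dump ships four delimited tables keyed by a case identification
number: demographics (DEMO), drug records (DRUG), adverse events coded as
MedDRA preferred terms (REAC), and medical history (HIST). This module reads
the tables under a configurable column mapping (real dumps carry Japanese
headers; nothing is hard-coded) and joins them into one ``CaseRecord`` per
case. Rows whose case id has no DEMO entry are collected into an orphan
report rather than dropped.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .dates import PartialDate, parse_partial_date
from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Involvement(str, enum.Enum):
    """Reporter-assigned role of a drug in the adverse event.

    ``UNKNOWN`` is the missing-value state for unmappable labels; analyses
    that include "all categories" treat it like any other category.
    """

    SUSPECTED = "suspected"
    CONCOMITANT = "concomitant"
    INTERACTION = "interaction"
    UNKNOWN = "unknown"


class TableKind(str, enum.Enum):
    DEMO = "DEMO"
    DRUG = "DRUG"
    REAC = "REAC"
    HIST = "HIST"


@dataclass(frozen=True)
class DemoEntry:
    case_id: str
    sex: Sex
    age_raw: str  # verbatim as reported: "20s", "adult", "", ...


@dataclass(frozen=True)
class DrugEntry:
    case_id: str
    drug_name: str
    involvement: Involvement
    dose_mg_per_day: Optional[float]
    start_date: Optional[PartialDate]


@dataclass(frozen=True)
class ReacEntry:
    case_id: str
    pt: str  # MedDRA preferred term
    onset_date: Optional[PartialDate]


@dataclass(frozen=True)
class HistEntry:
    case_id: str
    disease_pt: str


@dataclass
class CaseRecord:
    case_id: str
    demo: DemoEntry
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[ReacEntry] = field(default_factory=list)
    history: list[HistEntry] = field(default_factory=list)


@dataclass
class OrphanReport:
    """DRUG/REAC/HIST rows whose case id is absent from DEMO."""

    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[ReacEntry] = field(default_factory=list)
    history: list[HistEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.drugs) + len(self.reactions) + len(self.history)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.drugs:
            rows.append({"table": "DRUG", "case_id": e.case_id, "value": e.drug_name})
        for e in self.reactions:
            rows.append({"table": "REAC", "case_id": e.case_id, "value": e.pt})
        for e in self.history:
            rows.append({"table": "HIST", "case_id": e.case_id, "value": e.disease_pt})
        return pd.DataFrame(rows, columns=["table", "case_id", "value"])


# field -> column name used when no mapping is supplied (matches the
# synthetic-dump writer in pvonset.synth)
DEFAULT_MAPPINGS: dict[TableKind, dict[str, str]] = {
    TableKind.DEMO: {"case_id": "case_id", "sex": "sex", "age": "age"},
    TableKind.DRUG: {
        "case_id": "case_id",
        "drug_name": "drug_name",
        "involvement": "involvement",
        "dose_mg_per_day": "dose_mg_per_day",
        "start_date": "start_date",
    },
    TableKind.REAC: {"case_id": "case_id", "pt": "pt", "onset_date": "onset_date"},
    TableKind.HIST: {"case_id": "case_id", "disease_pt": "disease_pt"},
}

# observed label -> enum; lookups are case-folded. Covers the English labels
# the synthetic writer emits plus the Japanese labels of real dumps.
SEX_VALUE_MAP: dict[str, Sex] = {
    "male": Sex.MALE,
    "m": Sex.MALE,
    "男性": Sex.MALE,
    "female": Sex.FEMALE,
    "f": Sex.FEMALE,
    "女性": Sex.FEMALE,
}
INVOLVEMENT_VALUE_MAP: dict[str, Involvement] = {
    "suspected": Involvement.SUSPECTED,
    "suspected drug": Involvement.SUSPECTED,
    "被疑薬": Involvement.SUSPECTED,
    "concomitant": Involvement.CONCOMITANT,
    "concomitant drug": Involvement.CONCOMITANT,
    "併用薬": Involvement.CONCOMITANT,
    "interaction": Involvement.INTERACTION,
    "相互作用": Involvement.INTERACTION,
}


def normalize_drug_name(
    name: str, synonyms: Mapping[str, str] | None = None
) -> str:
    """Case-fold and trim a drug name; optionally map brand -> generic."""
    key = name.strip().casefold()
    if synonyms:
        key = synonyms.get(key, key)
    return key


def _parse_sex(value: str) -> Sex:
    return SEX_VALUE_MAP.get(value.strip().casefold(), Sex.UNKNOWN)


def _parse_involvement(value: str) -> Involvement:
    return INVOLVEMENT_VALUE_MAP.get(value.strip().casefold(), Involvement.UNKNOWN)


def _parse_dose(value: str) -> Optional[float]:
    value = value.strip()
    if not value:
        return None
    try:
        dose = float(value)
    except ValueError:
        return None
    return dose if dose >= 0 else None


def read_table(
    path: str | Path,
    table_kind: TableKind | str,
    mapping: Mapping[str, str] | None = None,
    delimiter: str = ",",
    encoding: str = "utf-8",
) -> list:
    """Read one of the four tables into typed entries.

    ``mapping`` maps the schema's field names to the file's column headers;
    fields absent from it fall back to the default header. Unmappable enum
    labels become the unknown/missing state, never an error; row count is
    preserved.
    """
    kind = TableKind(table_kind)
    colmap = dict(DEFAULT_MAPPINGS[kind])
    if mapping:
        unknown = set(mapping) - set(colmap)
        if unknown:
            raise ConfigurationError(
                f"mapping for {kind.value} names unknown fields: {sorted(unknown)}"
            )
        colmap.update(mapping)

    df = pd.read_csv(
        path, sep=delimiter, encoding=encoding, dtype=str, keep_default_na=False
    )
    missing = [col for col in colmap.values() if col not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{kind.value} file {path} lacks required column(s): {missing}"
        )

    def col(field_name: str) -> list[str]:
        return [str(v) for v in df[colmap[field_name]].tolist()]

    entries: list = []
    if kind is TableKind.DEMO:
        for cid, sex, age in zip(col("case_id"), col("sex"), col("age")):
            entries.append(DemoEntry(case_id=cid, sex=_parse_sex(sex), age_raw=age))
    elif kind is TableKind.DRUG:
        for cid, name, inv, dose, start in zip(
            col("case_id"),
            col("drug_name"),
            col("involvement"),
            col("dose_mg_per_day"),
            col("start_date"),
        ):
            entries.append(
                DrugEntry(
                    case_id=cid,
                    drug_name=name,
                    involvement=_parse_involvement(inv),
                    dose_mg_per_day=_parse_dose(dose),
                    start_date=parse_partial_date(start),
                )
            )
    elif kind is TableKind.REAC:
        for cid, pt, onset in zip(col("case_id"), col("pt"), col("onset_date")):
            entries.append(
                ReacEntry(case_id=cid, pt=pt, onset_date=parse_partial_date(onset))
            )
    else:
        for cid, pt in zip(col("case_id"), col("disease_pt")):
            entries.append(HistEntry(case_id=cid, disease_pt=pt))
    return entries


def build_cases(
    demo: Sequence[DemoEntry],
    drug: Sequence[DrugEntry] = (),
    reac: Sequence[ReacEntry] = (),
    hist: Sequence[HistEntry] = (),
) -> tuple[list[CaseRecord], OrphanReport]:
    """Relational join on the case identification number.

    Returns exactly one ``CaseRecord`` per distinct DEMO case id (in DEMO
    order) and an :class:`OrphanReport` of child rows whose id has no DEMO
    entry. Duplicate DEMO ids are a validation error.
    """
    seen: dict[str, CaseRecord] = {}
    dupes = []
    for d in demo:
        if d.case_id in seen:
            dupes.append(d.case_id)
        else:
            seen[d.case_id] = CaseRecord(case_id=d.case_id, demo=d)
    if dupes:
        raise ValidationError(f"duplicate DEMO rows for case id(s): {sorted(set(dupes))}")

    orphans = OrphanReport()
    for e in drug:
        (seen[e.case_id].drugs if e.case_id in seen else orphans.drugs).append(e)
    for e in reac:
        (seen[e.case_id].reactions if e.case_id in seen else orphans.reactions).append(e)
    for e in hist:
        (seen[e.case_id].history if e.case_id in seen else orphans.history).append(e)

    if len(orphans):
        logger.warning("join produced %d orphan child rows", len(orphans))
    return list(seen.values()), orphans


def filter_drug_cases(
    cases: Iterable[CaseRecord],
    drug_name: str,
    synonyms: Mapping[str, str] | None = None,
) -> list[CaseRecord]:
    """Cases with at least one record of ``drug_name`` in ANY involvement
    category (suspected, concomitant, or interaction). Order preserved."""
    if not drug_name or not drug_name.strip():
        raise ValueError("drug_name must be non-empty")
    target = normalize_drug_name(drug_name, synonyms)
    return [
        c
        for c in cases
        if any(normalize_drug_name(d.drug_name, synonyms) == target for d in c.drugs)
    ]
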