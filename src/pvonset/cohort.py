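"""Cohort construction: exclusion rules and the covariate vector.

Starting from the reports that mention the study drug, each case is either
excluded (unknown sex; unknown or non-numeric age; unknown study-drug dose;
lithium use with unknown dose) or reduced to one complete row of outcome +
covariates. Exclusions are attributed to the FIRST failing rule in the fixed
order sex -> age -> study-drug dose -> lithium dose, which makes the flow
ledger deterministic, and the ledger conserves counts:
``n_input = n_retained + sum(exclusions)``.

Covariates follow standard pharmacovigilance practice for antipsychotic
safety profiles: decade-banded age collapsed to five categories (<=29 as
reference), study-drug dose in three bands, antipsychotic polypharmacy,
lithium in three levels (none as reference), fluvoxamine, concomitant
antiepileptics (with a temporal rule: agents started strictly after the
seizure onset date do not count), and history of convulsive disorder.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError
from .jader import CaseRecord, DrugEntry, Sex, normalize_drug_name
from .smq import CaseFlags


class AgeCat(str, enum.Enum):
    LE29 = "le29"
    A30S = "30s"
    A40S = "40s"
    A50S = "50s"
    GE60 = "ge60"


class DoseCat(str, enum.Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


class LithiumCat(str, enum.Enum):
    NONE = "none"
    LOW = "low"
    HIGH = "high"


class ExclusionReason(str, enum.Enum):
    UNKNOWN_SEX = "unknown_sex"
    UNKNOWN_AGE = "unknown_age_or_nonnumeric"
    UNKNOWN_DOSE = "unknown_cloz_dose"
    UNKNOWN_LITHIUM_DOSE = "unknown_lithium_dose"


@dataclass(frozen=True)
class CohortRow:
    """One analyzable case: all fields are non-missing by construction."""

    case_id: str
    outcome_seizure: bool
    sex: Sex  # MALE or FEMALE only
    age_cat: AgeCat
    cloz_dose_cat: DoseCat
    polypharmacy: bool
    lithium_cat: LithiumCat
    fluvoxamine: bool
    antiepileptic: bool
    convulsive_history: bool


@dataclass
class ExclusionLedger:
    """Flow counts for the exclusion cascade (first-failing-rule attribution)."""

    n_input: int = 0
    n_retained: int = 0
    counts: dict[ExclusionReason, int] = field(
        default_factory=lambda: {r: 0 for r in ExclusionReason}
    )

    @property
    def n_excluded(self) -> int:
        return sum(self.counts.values())

    def check(self) -> None:
        if self.n_input != self.n_retained + self.n_excluded:
            raise AssertionError("ledger does not conserve counts")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "excluded": {r.value: c for r, c in self.counts.items()},
        }


@dataclass
class CohortConfig:
    """Everything needed to turn flagged cases into cohort rows."""

    drug_name: str = "clozapine"
    dose_low_edge: float = 200.0  # < edge -> low
    dose_high_edge: float = 400.0  # > edge -> high; [low, high] closed -> medium
    lithium_edge: float = 600.0  # <= edge -> low, > edge -> high
    lithium_names: frozenset[str] = frozenset({"lithium", "lithium carbonate"})
    fluvoxamine_names: frozenset[str] = frozenset({"fluvoxamine"})
    antipsychotics: frozenset[str] = frozenset()
    antiepileptics: frozenset[str] = frozenset()
    dose_rule: str = "max"  # max | first | mean over a case's study-drug rows
    synonyms: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        if not self.antipsychotics:
            self.antipsychotics = bundled_drug_list("antipsychotics.txt")
        if not self.antiepileptics:
            self.antiepileptics = bundled_drug_list("antiepileptics.txt")
        if self.dose_rule not in ("max", "first", "mean"):
            raise ValidationError(f"unknown dose rule: {self.dose_rule}")
        if not (0 < self.dose_low_edge <= self.dose_high_edge):
            raise ValidationError("dose band edges must be positive and ordered")


def _parse_drug_list(text: str, source: str) -> frozenset[str]:
    names = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            names.append(normalize_drug_name(line))
    if not names:
        raise ValidationError(f"drug list {source} is empty")
    return frozenset(names)


def load_drug_list(path: str | Path) -> frozenset[str]:
    """Plain-text drug list: one generic name per line, ``#`` comments."""
    return _parse_drug_list(Path(path).read_text(encoding="utf-8"), str(path))


@lru_cache(maxsize=None)
def bundled_drug_list(name: str) -> frozenset[str]:
    text = resources.files("pvonset.data").joinpath(name).read_text(encoding="utf-8")
    return _parse_drug_list(text, name)


_AGE_RE = re.compile(r"^\s*(\d+)\s*(?:s|代)?\s*$", re.IGNORECASE)


def categorize_age(age_raw: str) -> Optional[AgeCat]:
    """Decade-band age string to category; ``None`` means exclusion.

    Accepts "20s", "20代", or a bare decade "20". Non-numeric labels such as
    "adult", "child", "elderly" (or an empty field) are not categorizable.
    """
    m = _AGE_RE.match(age_raw or "")
    if m is None:
        return None
    decade = (int(m.group(1)) // 10) * 10
    if decade <= 20:
        return AgeCat.LE29
    if decade == 30:
        return AgeCat.A30S
    if decade == 40:
        return AgeCat.A40S
    if decade == 50:
        return AgeCat.A50S
    return AgeCat.GE60


def categorize_cloz_dose(
    dose_mg_per_day: Optional[float],
    low_edge: float = 200.0,
    high_edge: float = 400.0,
) -> Optional[DoseCat]:
    """Dose band: < low_edge -> low; [low_edge, high_edge] -> medium;
    > high_edge -> high; missing -> ``None`` (exclusion)."""
    if dose_mg_per_day is None:
        return None
    if dose_mg_per_day < low_edge:
        return DoseCat.LOW
    if dose_mg_per_day <= high_edge:
        return DoseCat.MEDIUM
    return DoseCat.HIGH


def _drug_rows(case: CaseRecord, names: frozenset[str] | str, cfg: CohortConfig) -> list[DrugEntry]:
    targets = {names} if isinstance(names, str) else set(names)
    targets = {normalize_drug_name(t) for t in targets}
    return [
        d
        for d in case.drugs
        if normalize_drug_name(d.drug_name, cfg.synonyms) in targets
    ]


def _resolve_dose(entries: Sequence[DrugEntry], rule: str) -> Optional[float]:
    doses = [d.dose_mg_per_day for d in entries if d.dose_mg_per_day is not None]
    if not doses:
        return None
    if rule == "max":
        return max(doses)
    if rule == "first":
        return doses[0]
    return sum(doses) / len(doses)


def resolve_cloz_dose(case: CaseRecord, cfg: CohortConfig | None = None) -> Optional[float]:
    """One daily dose per case from possibly several study-drug rows.

    Default rule is the maximum non-missing dose (peak exposure); missing if
    every row's dose is missing.
    """
    cfg = cfg or CohortConfig()
    return _resolve_dose(_drug_rows(case, cfg.drug_name, cfg), cfg.dose_rule)


def categorize_lithium(case: CaseRecord, cfg: CohortConfig | None = None) -> Optional[LithiumCat]:
    """No lithium row -> none; dose <= edge -> low; > edge -> high;
    lithium present with every dose missing -> ``None`` (exclusion)."""
    cfg = cfg or CohortConfig()
    rows = _drug_rows(case, cfg.lithium_names, cfg)
    if not rows:
        return LithiumCat.NONE
    dose = _resolve_dose(rows, cfg.dose_rule)
    if dose is None:
        return None
    return LithiumCat.LOW if dose <= cfg.lithium_edge else LithiumCat.HIGH


def flag_polypharmacy(case: CaseRecord, cfg: CohortConfig | None = None) -> bool:
    """At least one antipsychotic other than the study drug on the case."""
    cfg = cfg or CohortConfig()
    study = normalize_drug_name(cfg.drug_name, cfg.synonyms)
    return any(
        normalize_drug_name(d.drug_name, cfg.synonyms) in cfg.antipsychotics
        and normalize_drug_name(d.drug_name, cfg.synonyms) != study
        for d in case.drugs
    )


def flag_fluvoxamine(case: CaseRecord, cfg: CohortConfig | None = None) -> bool:
    cfg = cfg or CohortConfig()
    return bool(_drug_rows(case, cfg.fluvoxamine_names, cfg))


def flag_antiepileptic(
    case: CaseRecord, flags: CaseFlags, cfg: CohortConfig | None = None
) -> bool:
    """Concomitant antiepileptic use with a temporal rule.

    Agents initiated strictly after the seizure onset date are
    non-concomitant (they respond to the event rather than precede it); the
    rule can only fire when both the onset date and a start date are
    complete. Missing or partial start dates count as concomitant — there is
    no evidence of "after onset".
    """
    cfg = cfg or CohortConfig()
    rows = _drug_rows(case, cfg.antiepileptics, cfg)
    if not rows:
        return False
    if not (flags.is_seizure_case and flags.seizure_onset_date is not None):
        return True
    onset = flags.seizure_onset_date.to_date()
    for d in rows:
        if d.start_date is None or not d.start_date.complete:
            return True  # cannot show it started after onset
        if d.start_date.to_date() <= onset:
            return True
    return False  # every dated row started after onset


def build_cohort(
    cases: Iterable[CaseRecord],
    flags_by_case: Mapping[str, CaseFlags],
    cfg: CohortConfig | None = None,
) -> tuple[list[CohortRow], ExclusionLedger]:
    """Apply the exclusion cascade and emit one row per retained case."""
    cfg = cfg or CohortConfig()
    ledger = ExclusionLedger()
    rows: list[CohortRow] = []
    for case in cases:
        ledger.n_input += 1
        flags = flags_by_case[case.case_id]

        if case.demo.sex is Sex.UNKNOWN:
            ledger.counts[ExclusionReason.UNKNOWN_SEX] += 1
            continue
        age_cat = categorize_age(case.demo.age_raw)
        if age_cat is None:
            ledger.counts[ExclusionReason.UNKNOWN_AGE] += 1
            continue
        dose_cat = categorize_cloz_dose(
            resolve_cloz_dose(case, cfg), cfg.dose_low_edge, cfg.dose_high_edge
        )
        if dose_cat is None:
            ledger.counts[ExclusionReason.UNKNOWN_DOSE] += 1
            continue
        lithium_cat = categorize_lithium(case, cfg)
        if lithium_cat is None:
            ledger.counts[ExclusionReason.UNKNOWN_LITHIUM_DOSE] += 1
            continue

        rows.append(
            CohortRow(
                case_id=case.case_id,
                outcome_seizure=flags.is_seizure_case,
                sex=case.demo.sex,
                age_cat=age_cat,
                cloz_dose_cat=dose_cat,
                polypharmacy=flag_polypharmacy(case, cfg),
                lithium_cat=lithium_cat,
                fluvoxamine=flag_fluvoxamine(case, cfg),
                antiepileptic=flag_antiepileptic(case, flags, cfg),
                convulsive_history=flags.has_convulsive_history,
            )
        )
        ledger.n_retained += 1
    ledger.check()
    return rows, ledger


def cohort_to_frame(rows: Sequence[CohortRow]):
    """Cohort as a tidy DataFrame (documented column order)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "outcome_seizure": int(r.outcome_seizure),
                "sex": r.sex.value,
                "age_cat": r.age_cat.value,
                "cloz_dose_cat": r.cloz_dose_cat.value,
                "polypharmacy": int(r.polypharmacy),
                "lithium_cat": r.lithium_cat.value,
                "fluvoxamine": int(r.fluvoxamine),
                "antiepileptic": int(r.antiepileptic),
                "convulsive_history": int(r.convulsive_history),
            }
            for r in rows
        ],
        columns=[
            "case_id",
            "outcome_seizure",
            "sex",
            "age_cat",
            "cloz_dose_cat",
            "polypharmacy",
            "lithium_cat",
            "fluvoxamine",
            "antiepileptic",
            "convulsive_history",
        ],
    )
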