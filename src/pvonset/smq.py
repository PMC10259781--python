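"""Standardized MedDRA Query (SMQ) term sets and case flagging.

An SMQ is a curated set of preferred terms (PTs) defining a medical concept;
the narrow scope is its high-specificity subset. Here an SMQ is just a named
term set loaded from a plain-text file (one PT per line, ``#`` comments,
optional ``code:``/``scope:`` header lines). A case is a *seizure case* when
any adverse-event PT is in the set, and has a *history of convulsive
disorder* when any medical-history disease PT is in the set.

The licensed MedDRA dictionary cannot be redistributed, so the bundled term
list is a small synthetic demo subset; real analyses supply their own file
(the convulsions SMQ, code 20000079 narrow scope, has 101 PTs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

from .dates import PartialDate
from .errors import ValidationError
from .jader import CaseRecord

logger = logging.getLogger(__name__)


def _norm(term: str) -> str:
    return term.strip().casefold()


@dataclass(frozen=True)
class TermQuery:
    """A named set of preferred terms; matching is exact after case-folding
    and whitespace trimming."""

    smq_code: str
    scope: str  # "narrow" or "broad"
    terms: frozenset[str]  # normalized

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValidationError("term set must be non-empty")

    def matches(self, pt: str) -> bool:
        return _norm(pt) in self.terms


@dataclass(frozen=True)
class CaseFlags:
    case_id: str
    is_seizure_case: bool
    seizure_onset_date: Optional[PartialDate]  # earliest complete matching date
    has_convulsive_history: bool


def load_term_list(path: str | Path) -> TermQuery:
    """Load a term-list file.

    Format: one PT per line; ``#`` starts a comment; optional header lines
    ``code: <smq code>`` and ``scope: narrow|broad``. Duplicate terms are
    collapsed with a warning. An empty list is a validation error.
    """
    code = ""
    scope = "narrow"
    terms: list[str] = []
    text = Path(path).read_text(encoding="utf-8")
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        low = line.casefold()
        if low.startswith("code:"):
            code = line.split(":", 1)[1].strip()
        elif low.startswith("scope:"):
            scope = line.split(":", 1)[1].strip().casefold()
        else:
            terms.append(line)
    normalized = [_norm(t) for t in terms]
    unique = frozenset(normalized)
    if len(unique) < len(normalized):
        logger.warning(
            "term list %s contains %d duplicate term(s); set semantics applied",
            path,
            len(normalized) - len(unique),
        )
    if not unique:
        raise ValidationError(f"term list {path} contains no terms")
    return TermQuery(smq_code=code, scope=scope, terms=unique)


def bundled_demo_terms() -> TermQuery:
    """The small demo convulsions term list shipped with the package
    (synthetic subset, not the licensed SMQ)."""
    ref = resources.files("pvonset.data").joinpath("smq_convulsions_demo.txt")
    with resources.as_file(ref) as p:
        return load_term_list(p)


def bundled_demo_terms_path():
    """Filesystem path of the bundled demo term list (editable installs)."""
    from pathlib import Path

    ref = resources.files("pvonset.data").joinpath("smq_convulsions_demo.txt")
    with resources.as_file(ref) as p:
        return Path(p)


def flag_case(case: CaseRecord, q: TermQuery) -> CaseFlags:
    """Flag one case against a term query.

    The seizure onset date is the earliest *complete* onset date over
    matching adverse events (several seizure PTs in one report are common);
    partial or missing dates leave the case a seizure case but without a
    usable onset date.
    """
    matching = [r for r in case.reactions if q.matches(r.pt)]
    onset: Optional[PartialDate] = None
    complete_dates = [
        r.onset_date for r in matching if r.onset_date is not None and r.onset_date.complete
    ]
    if complete_dates:
        onset = min(complete_dates, key=lambda d: d.to_date())
    return CaseFlags(
        case_id=case.case_id,
        is_seizure_case=bool(matching),
        seizure_onset_date=onset,
        has_convulsive_history=any(q.matches(h.disease_pt) for h in case.history),
    )
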