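"""Calendar dates that may be incomplete.

Spontaneous-report databases record dates at whatever precision the reporter
supplied: a full day, a year-month, or a bare year. Ingest preserves that
precision; only analyses that need day resolution (time-to-onset, temporal
ordering of drug start vs event onset) demand a *complete* date, and they
treat partial dates as missing rather than imputing them.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from typing import Optional

_ISO_RE = re.compile(r"^(\d{4})(?:-(\d{1,2})(?:-(\d{1,2}))?)?$")
_COMPACT_RE = re.compile(r"^(\d{4})(\d{2})?(\d{2})?$")


@dataclass(frozen=True, order=False)
class PartialDate:
    """A calendar date known to year, year-month, or full-day precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day given without month")
        if self.month is not None and not 1 <= self.month <= 12:
            raise ValueError(f"month out of range: {self.month}")
        if self.day is not None:
            # delegates day-of-month validation to datetime
            _dt.date(self.year, self.month, self.day)

    @property
    def complete(self) -> bool:
        return self.month is not None and self.day is not None

    def to_date(self) -> _dt.date:
        if not self.complete:
            raise ValueError(f"partial date {self} has no day resolution")
        return _dt.date(self.year, self.month, self.day)

    def __str__(self) -> str:
        if self.month is None:
            return f"{self.year:04d}"
        if self.day is None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"

    @classmethod
    def from_date(cls, d: _dt.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)


def parse_partial_date(text: str | None) -> Optional[PartialDate]:
    """Parse ``YYYY[-MM[-DD]]`` or compact ``YYYY[MM[DD]]`` strings.

    Empty, whitespace-only, or unparseable values return ``None`` (missing):
    ingest never raises on a malformed date, it degrades to missing.
    """
    if text is None:
        return None
    text = text.strip()
    if not text:
        return None
    m = _ISO_RE.match(text) or _COMPACT_RE.match(text)
    if m is None:
        return None
    year = int(m.group(1))
    month = int(m.group(2)) if m.group(2) else None
    day = int(m.group(3)) if m.group(3) else None
    try:
        return PartialDate(year, month, day)
    except ValueError:
        return None


def days_between(start: PartialDate, end: PartialDate) -> int:
    """Whole days from ``start`` to ``end`` (both complete)."""
    return (end.to_date() - start.to_date()).days
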