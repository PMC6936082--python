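"""Core domain types for multi-source Indigenous-status resolution.

A person appears in up to four linked collections: the cancer registry
(NSWCR), hospital admissions (APDC), emergency department presentations
(EDDC) and the cause-of-death unit record file (COD_URF).  Each record
carries a three-valued Indigenous-status field; the registry's own status
is held at person level and is the variable being enhanced.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field


class Status(str, enum.Enum):
    """Three-valued recorded Indigenous status.

    ``UNKNOWN`` is a legitimate recorded value but is never a final
    reported status: at reporting time it is folded into
    ``NON_ABORIGINAL``.
    """

    ABORIGINAL = "aboriginal"
    NON_ABORIGINAL = "non_aboriginal"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: str) -> "Status":
        """Parse a status label case-insensitively ('non-aboriginal' ok)."""
        key = str(text).strip().lower().replace("-", "_").replace(" ", "_")
        try:
            return cls(key)
        except ValueError:
            raise ValueError(f"unrecognised status value: {text!r}") from None


class Source(str, enum.Enum):
    """The four linked data collections."""

    NSWCR = "NSWCR"
    APDC = "APDC"
    EDDC = "EDDC"
    COD_URF = "COD_URF"

    @classmethod
    def parse(cls, text: str) -> "Source":
        key = str(text).strip().upper().replace("-", "_")
        try:
            return cls(key)
        except ValueError:
            raise ValueError(f"unrecognised source: {text!r}") from None


#: Sources whose records contribute units of information to the
#: enhancement rules.  The registry itself is excluded by default: it is
#: the variable being corrected, and an Aboriginal registry status is
#: already decisive through the precedence rule.
DEFAULT_UNIT_SOURCES: frozenset[Source] = frozenset(
    {Source.APDC, Source.EDDC, Source.COD_URF}
)

#: Fixed tie-break order for same-date units.
_SOURCE_ORDER = {Source.APDC: 0, Source.EDDC: 1, Source.COD_URF: 2, Source.NSWCR: 3}


class Method(str, enum.Enum):
    """The four enhancement algorithms."""

    EVER = "ever"
    MOST_RECENT = "most_recent"
    WEIGHT_OF_EVIDENCE = "weight_of_evidence"
    MULTI_STAGE_MEDIAN = "multi_stage_median"

    @classmethod
    def parse(cls, text: str) -> "Method":
        key = str(text).strip().lower().replace("-", "_")
        aliases = {
            "ever_reported": "ever",
            "woe": "weight_of_evidence",
            "msm": "multi_stage_median",
            "mostrecent": "most_recent",
        }
        key = aliases.get(key, key)
        try:
            return cls(key)
        except ValueError:
            raise ValueError(f"unrecognised method: {text!r}") from None


class ChangeOrigin(str, enum.Enum):
    """What the registry status was before an enhancement changed it."""

    FROM_NON_ABORIGINAL = "from_non_aboriginal"
    FROM_UNKNOWN = "from_unknown"
    NOT_CHANGED = "not_changed"


@dataclass(frozen=True)
class SourceRecord:
    """One dated status observation of a person from one collection."""

    person_id: str
    source: Source
    event_date: dt.date
    status: Status


@dataclass(frozen=True)
class Unit:
    """A unit of information: one record with a known (non-unknown) status."""

    source: Source
    date: dt.date
    aboriginal: bool


@dataclass
class PersonEvidence:
    """Everything known about one person's recorded status.

    ``nswcr_status`` is the registry's person-level status (the variable
    being enhanced); ``records`` are the dated observations from the
    other collections (and possibly the registry, if configured as a
    unit source).
    """

    person_id: str
    nswcr_status: Status
    records: list[SourceRecord] = field(default_factory=list)


@dataclass(frozen=True)
class EnhancedStatus:
    """A person's final status under one enhancement method."""

    person_id: str
    base_status: Status
    final_status: Status  # ABORIGINAL or NON_ABORIGINAL, never UNKNOWN
    changed: bool
    change_origin: ChangeOrigin

    @property
    def aboriginal(self) -> bool:
        return self.final_status is Status.ABORIGINAL


def fold_unknown(status: Status) -> Status:
    """Fold UNKNOWN into NON_ABORIGINAL, as done at reporting time."""
    if status is Status.ABORIGINAL:
        return Status.ABORIGINAL
    return Status.NON_ABORIGINAL


def unit_sort_key(unit: Unit, index: int) -> tuple:
    """Date ascending, ties by fixed source order, then input order."""
    return (unit.date, _SOURCE_ORDER[unit.source], index)
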