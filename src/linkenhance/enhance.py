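"""The four status-enhancement algorithms and the precedence rules.

All four methods consume *units of information* — dated records with a
known (non-unknown) status from the admissions, emergency-department and
cause-of-death collections — and decide whether a person recorded as
non-Aboriginal or unknown on the cancer registry should be reported as
Aboriginal.  Two rules are applied before any algorithm:

* a person Aboriginal on the registry keeps that status (only upward
  correction of registry under-recording is attempted), and
* a person Aboriginal on a death certificate is taken to be Aboriginal,
  next-of-kin report being considered reliable.

The methods:

``EVER``
    Aboriginal if recorded as Aboriginal at least once in any source.
``MOST_RECENT``
    Status of the most recently dated unit.
``WEIGHT_OF_EVIDENCE``
    Aboriginal if at least two of three-or-more units say Aboriginal,
    or at least one of one-or-two units does.
``MULTI_STAGE_MEDIAN``
    Weight of evidence applied within each source first, then across
    the one-per-source results.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence

import pandas as pd

from .statuses import (
    DEFAULT_UNIT_SOURCES,
    ChangeOrigin,
    EnhancedStatus,
    Method,
    PersonEvidence,
    Source,
    SourceRecord,
    Status,
    Unit,
    fold_unknown,
    unit_sort_key,
)

__all__ = [
    "extract_units",
    "apply_precedence",
    "ever_reported",
    "most_recent",
    "weight_of_evidence",
    "multi_stage_median",
    "enhance_person",
    "enhance_cohort",
    "enhance_frame",
    "evidence_from_frame",
]


def extract_units(
    evidence: PersonEvidence,
    unit_sources: Iterable[Source] = DEFAULT_UNIT_SOURCES,
) -> list[Unit]:
    """Turn a person's records into an ordered list of units.

    One unit per record with a known status; unknown-status records
    contribute nothing.  Ordered by date ascending, same-date ties by
    the fixed source order APDC < EDDC < COD_URF, then input order.
    """
    sources = frozenset(unit_sources)
    units = [
        Unit(r.source, r.event_date, r.status is Status.ABORIGINAL)
        for r in evidence.records
        if r.source in sources and r.status is not Status.UNKNOWN
    ]
    return [u for _, u in sorted(enumerate(units), key=lambda t: unit_sort_key(t[1], t[0]))]


def apply_precedence(evidence: PersonEvidence) -> tuple[bool, Status | None]:
    """Registry / death-certificate precedence.

    Returns ``(eligible, forced_status)``: a person Aboriginal on the
    registry or on any death record is Aboriginal outright and is not
    eligible for algorithmic enhancement; everyone else is eligible.
    """
    if evidence.nswcr_status is Status.ABORIGINAL:
        return False, Status.ABORIGINAL
    for record in evidence.records:
        if record.source is Source.COD_URF and record.status is Status.ABORIGINAL:
            return False, Status.ABORIGINAL
    return True, None


def _woe_rule(flags: Sequence[bool]) -> bool | None:
    """The weight-of-evidence decision on a list of Aboriginal flags.

    None when there are no units (the rule is silent; callers fall back
    to the base status).
    """
    n = len(flags)
    if n == 0:
        return None
    n_ab = sum(flags)
    if n >= 3:
        return n_ab >= 2
    return n_ab >= 1


def ever_reported(units: Sequence[Unit], base_status: Status) -> Status:
    """Aboriginal iff any unit says Aboriginal; otherwise the base status
    with unknown folded to non-Aboriginal."""
    if any(u.aboriginal for u in units):
        return Status.ABORIGINAL
    return fold_unknown(base_status)


def most_recent(units: Sequence[Unit], base_status: Status) -> Status:
    """Status of the most recently dated unit.

    Same-date ties resolve to Aboriginal if any tied unit is Aboriginal
    (positive-identification stance).  No units: base status.
    """
    if not units:
        return fold_unknown(base_status)
    last_date = max(u.date for u in units)
    tied = [u for u in units if u.date == last_date]
    if any(u.aboriginal for u in tied):
        return Status.ABORIGINAL
    return Status.NON_ABORIGINAL


def weight_of_evidence(units: Sequence[Unit], base_status: Status) -> Status:
    """Aboriginal iff ≥2 of ≥3 units, or ≥1 of 1–2 units, say Aboriginal."""
    decision = _woe_rule([u.aboriginal for u in units])
    if decision is None:
        return fold_unknown(base_status)
    return Status.ABORIGINAL if decision else Status.NON_ABORIGINAL


def multi_stage_median(units: Sequence[Unit], base_status: Status) -> Status:
    """Weight of evidence within each source, then across sources.

    Stage 1 applies the weight-of-evidence rule to each source having at
    least one unit, producing one source-level result; stage 2 applies
    the same rule to those results, one unweighted unit per source.
    Sources with no units contribute nothing; no units at all falls back
    to the base status.
    """
    by_source: dict[Source, list[bool]] = defaultdict(list)
    for u in units:
        by_source[u.source].append(u.aboriginal)
    stage1 = [_woe_rule(flags) for flags in by_source.values()]
    decision = _woe_rule([d for d in stage1 if d is not None])
    if decision is None:
        return fold_unknown(base_status)
    return Status.ABORIGINAL if decision else Status.NON_ABORIGINAL


_ALGORITHMS = {
    Method.EVER: ever_reported,
    Method.MOST_RECENT: most_recent,
    Method.WEIGHT_OF_EVIDENCE: weight_of_evidence,
    Method.MULTI_STAGE_MEDIAN: multi_stage_median,
}


def enhance_person(
    evidence: PersonEvidence,
    method: Method,
    unit_sources: Iterable[Source] = DEFAULT_UNIT_SOURCES,
) -> EnhancedStatus:
    """Resolve one person's final status under one method.

    Precedence is applied first; only eligible persons (registry status
    non-Aboriginal or unknown, no Aboriginal death record) go through
    the selected algorithm.
    """
    base = evidence.nswcr_status
    eligible, forced = apply_precedence(evidence)
    if not eligible:
        final = forced
    else:
        units = extract_units(evidence, unit_sources)
        final = _ALGORITHMS[method](units, base)

    changed = final is Status.ABORIGINAL and base is not Status.ABORIGINAL
    if not changed:
        origin = ChangeOrigin.NOT_CHANGED
    elif base is Status.UNKNOWN:
        origin = ChangeOrigin.FROM_UNKNOWN
    else:
        origin = ChangeOrigin.FROM_NON_ABORIGINAL
    return EnhancedStatus(
        person_id=evidence.person_id,
        base_status=base,
        final_status=fold_unknown(final),
        changed=changed,
        change_origin=origin,
    )


def enhance_cohort(
    evidences: Sequence[PersonEvidence],
    method: Method,
    unit_sources: Iterable[Source] = DEFAULT_UNIT_SOURCES,
) -> list[EnhancedStatus]:
    """Apply one method to a whole cohort (one evidence item per person)."""
    seen: set[str] = set()
    out = []
    for ev in evidences:
        if ev.person_id in seen:
            raise ValueError(f"duplicate person_id: {ev.person_id!r}")
        seen.add(ev.person_id)
        out.append(enhance_person(ev, method, unit_sources))
    return out


def evidence_from_frame(
    records: pd.DataFrame,
    persons: pd.DataFrame,
) -> list[PersonEvidence]:
    """Build per-person evidence from tabular inputs.

    ``records`` needs columns person_id/source/event_date/status;
    ``persons`` needs person_id and nswcr_status (one row per person —
    typically the distinct persons of the case file).  Persons with no
    records still get an (empty) evidence entry.
    """
    dup = persons["person_id"].duplicated()
    if dup.any():
        first = persons.loc[dup, "person_id"].iloc[0]
        raise ValueError(f"duplicate person_id: {first!r}")

    grouped: dict[str, list[SourceRecord]] = defaultdict(list)
    for row in records.itertuples(index=False):
        src = Source.parse(row.source)
        if src is Source.NSWCR:
            continue  # registry status arrives person-level via `persons`
        date = row.event_date
        if isinstance(date, str):
            date = pd.Timestamp(date).date()
        elif isinstance(date, pd.Timestamp):
            date = date.date()
        grouped[row.person_id].append(
            SourceRecord(row.person_id, src, date, Status.parse(row.status))
        )

    return [
        PersonEvidence(
            person_id=row.person_id,
            nswcr_status=Status.parse(row.nswcr_status),
            records=grouped.get(row.person_id, []),
        )
        for row in persons.itertuples(index=False)
    ]


def enhance_frame(
    records: pd.DataFrame,
    persons: pd.DataFrame,
    methods: Sequence[Method] = tuple(Method),
    unit_sources: Iterable[Source] = DEFAULT_UNIT_SOURCES,
) -> pd.DataFrame:
    """Run several methods over a tabular cohort.

    Returns one row per person with columns ``person_id``,
    ``base_status`` and, per method m, ``<m>_status`` (aboriginal /
    non_aboriginal), ``<m>_changed`` and ``<m>_origin``.
    """
    evidences = evidence_from_frame(records, persons)
    out: dict[str, list] = {
        "person_id": [ev.person_id for ev in evidences],
        "base_status": [ev.nswcr_status.value for ev in evidences],
    }
    for method in methods:
        results = [enhance_person(ev, method, unit_sources) for ev in evidences]
        out[f"{method.value}_status"] = [r.final_status.value for r in results]
        out[f"{method.value}_changed"] = [r.changed for r in results]
        out[f"{method.value}_origin"] = [r.change_origin.value for r in results]
    return pd.DataFrame(out)
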