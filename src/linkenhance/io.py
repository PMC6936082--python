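"""CSV readers/writers for the pipeline's tabular schemas.

Fixed dialect: UTF-8, comma-separated, header row, ISO-8601 dates.
Readers validate columns up front (schema errors name the missing
column) and report malformed rows with their line numbers.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import pandas as pd

from .statuses import Source, Status

__all__ = [
    "SchemaError",
    "read_records",
    "read_cases",
    "read_truth",
    "read_population",
    "write_table",
]

RECORD_COLUMNS = ["person_id", "source", "event_date", "status"]
CASE_COLUMNS = [
    "case_id", "person_id", "diagnosis_year", "age", "sex", "site_code",
    "site_group", "spread", "remoteness", "seifa_quintile", "nswcr_status",
]
TRUTH_COLUMNS = ["person_id", "true_status"]
POPULATION_COLUMNS = ["sex", "age_band", "year", "group", "persons"]


class SchemaError(ValueError):
    """An input file does not match its expected column schema."""


def _load(path, required: list[str], what: str) -> pd.DataFrame:
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(
            f"{what} file {path} is missing required column(s): {missing}"
        )
    return table


def _parse_column(table: pd.DataFrame, column: str, parser, what: str) -> list:
    """Apply a parser row-wise, collecting bad rows with CSV line numbers."""
    values, bad = [], []
    for i, raw in enumerate(table[column]):
        try:
            values.append(parser(raw))
        except (ValueError, TypeError) as exc:
            bad.append((i + 2, str(exc)))  # +2: header row + 1-based lines
            values.append(None)
    if bad:
        shown = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:5])
        raise ValueError(
            f"{len(bad)} bad row(s) in {what} column {column!r}: {shown}"
        )
    return values


def _parse_date(raw: str) -> dt.date:
    return dt.date.fromisoformat(str(raw).strip())


def read_records(path) -> pd.DataFrame:
    """Read dated status observations (person_id,source,event_date,status)."""
    table = _load(path, RECORD_COLUMNS, "records")
    table = table[RECORD_COLUMNS].copy()
    table["source"] = [s.value for s in _parse_column(table, "source", Source.parse, "records")]
    table["status"] = [s.value for s in _parse_column(table, "status", Status.parse, "records")]
    table["event_date"] = _parse_column(table, "event_date", _parse_date, "records")
    return table


def read_cases(path) -> pd.DataFrame:
    """Read cancer cases with demographic and cancer stratifiers."""
    table = _load(path, CASE_COLUMNS, "cases")
    table = table[CASE_COLUMNS].copy()
    table["nswcr_status"] = [
        s.value for s in _parse_column(table, "nswcr_status", Status.parse, "cases")
    ]
    for col in ("diagnosis_year", "age", "seifa_quintile"):
        table[col] = _parse_column(table, col, int, "cases")
    return table


def read_truth(path) -> pd.DataFrame:
    """Read simulated ground-truth statuses (person_id,true_status)."""
    table = _load(path, TRUTH_COLUMNS, "truth")
    table = table[TRUTH_COLUMNS].copy()
    table["true_status"] = [
        s.value for s in _parse_column(table, "true_status", Status.parse, "truth")
    ]
    return table


def read_population(path) -> pd.DataFrame:
    """Read denominator strata (sex,age_band,year,group,persons)."""
    table = _load(path, POPULATION_COLUMNS, "population")
    table = table[POPULATION_COLUMNS].copy()
    for col in ("age_band", "year", "persons"):
        table[col] = _parse_column(table, col, int, "population")
    if (table["persons"] < 0).any():
        raise ValueError("population counts must be non-negative")
    return table


def write_table(table: pd.DataFrame, path) -> Path:
    """Write a table in the fixed CSV dialect; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path
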