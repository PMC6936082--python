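"""End-to-end driver: read inputs, enhance statuses, report tables.

`run_pipeline` composes the stages deterministically and writes the
count table (per configured stratifier), the rate table, the per-person
status assignments, a recovery summary when a truth file is present,
and a machine-readable run manifest.  On any stage failure the partial
outputs written so far are removed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .enhance import enhance_frame
from .io import read_cases, read_population, read_records, read_truth, write_table
from .rates import build_count_table, build_rate_table, load_standard_population
from .simulate import evaluate_recovery
from .statuses import Method, Source

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

DEFAULT_STRATIFIERS = (
    "sex", "diagnosis_year", "site_group", "spread", "remoteness", "seifa_quintile",
)


class PipelineConfig(BaseModel):
    """Paths and options for one pipeline run."""

    records_path: Path
    cases_path: Path
    population_path: Path
    truth_path: Optional[Path] = None
    out_dir: Path = Path("pipeline_out")
    methods: tuple[str, ...] = tuple(m.value for m in Method)
    unit_sources: tuple[str, ...] = ("APDC", "EDDC", "COD_URF")
    stratifiers: tuple[str, ...] = DEFAULT_STRATIFIERS
    standard_population: Optional[Path] = None  # None -> packaged 2001 Australian
    ci_method: str = Field(default="gamma", pattern="^(gamma|normal)$")
    round_dp: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def parsed_methods(self) -> list[Method]:
        return [Method.parse(m) for m in self.methods]

    def parsed_unit_sources(self) -> frozenset[Source]:
        return frozenset(Source.parse(s) for s in self.unit_sources)


@dataclasses.dataclass
class PipelineResult:
    """Paths of everything a run wrote, plus the in-memory tables."""

    out_dir: Path
    statuses: pd.DataFrame
    count_tables: dict[str, pd.DataFrame]
    rate_table: pd.DataFrame
    recovery: Optional[pd.DataFrame]
    manifest: dict


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run enhance→count→rate→recovery over files on disk.

    Deterministic given the input files and configuration.  Outputs are
    written under ``config.out_dir``; partial outputs are removed if any
    stage fails.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        with _stage("read"):
            records = read_records(config.records_path)
            cases = read_cases(config.cases_path)
            population = read_population(config.population_path)
            truth = read_truth(config.truth_path) if config.truth_path else None
            standard = load_standard_population(
                str(config.standard_population) if config.standard_population else None
            )

        with _stage("enhance"):
            methods = config.parsed_methods()
            persons = cases[["person_id", "nswcr_status"]].drop_duplicates("person_id")
            statuses = enhance_frame(
                records, persons, methods, config.parsed_unit_sources()
            )
            written.append(write_table(statuses, out_dir / "statuses.csv"))

        method_names = tuple(m.value for m in methods)
        with _stage("count_tables"):
            count_tables = {}
            for strat in config.stratifiers:
                table = build_count_table(
                    cases, statuses, strat, method_names, config.round_dp
                )
                count_tables[strat] = table
                written.append(write_table(table, out_dir / f"counts_by_{strat}.csv"))

        with _stage("rate_table"):
            years = (int(cases["diagnosis_year"].min()), int(cases["diagnosis_year"].max()))
            rate_table = build_rate_table(
                cases, statuses, population, standard, years,
                methods=method_names, ci_method=config.ci_method,
                round_dp=config.round_dp,
            )
            written.append(write_table(rate_table, out_dir / "rate_table.csv"))

        recovery_frame = None
        if truth is not None:
            with _stage("recovery"):
                rows = [
                    dataclasses.asdict(evaluate_recovery(truth, statuses, m))
                    for m in method_names
                ]
                recovery_frame = pd.DataFrame(rows)
                written.append(write_table(recovery_frame, out_dir / "recovery.csv"))

        with _stage("manifest"):
            manifest = {
                "package_version": __version__,
                "python": platform.python_version(),
                "config": json.loads(config.model_dump_json()),
                "rows": {
                    "records": len(records),
                    "cases": len(cases),
                    "population": len(population),
                    "truth": len(truth) if truth is not None else 0,
                },
            }
            manifest_path = out_dir / "manifest.json"
            manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
            written.append(manifest_path)
    except _StageError:
        for path in written:
            path.unlink(missing_ok=True)
        raise

    return PipelineResult(
        out_dir=out_dir,
        statuses=statuses,
        count_tables=count_tables,
        rate_table=rate_table,
        recovery=recovery_frame,
        manifest=manifest,
    )
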