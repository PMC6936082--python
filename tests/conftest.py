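import datetime as dt

import pytest

from linkenhance.enhance import enhance_frame
from linkenhance.simulate import SimulationConfig, simulate_cohort
from linkenhance.statuses import PersonEvidence, Source, SourceRecord, Status


def make_evidence(nswcr="non_aboriginal", records=()):
    """Build PersonEvidence from (source, iso_date, status) triples."""
    return PersonEvidence(
        person_id="P1",
        nswcr_status=Status.parse(nswcr),
        records=[
            SourceRecord("P1", Source.parse(src), dt.date.fromisoformat(day), Status.parse(st))
            for src, day, st in records
        ],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 3000-person cohort with the default misrecording structure."""
    return simulate_cohort(SimulationConfig(n_persons=3000, seed=11))


@pytest.fixture(scope="session")
def small_statuses(small_cohort):
    persons = small_cohort.cases[["person_id", "nswcr_status"]].drop_duplicates("person_id")
    return enhance_frame(small_cohort.records, persons)
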