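from __future__ import annotations

from datetime import date

import pytest

from phenokit.concepts import ConceptSet, Disease, load_term_catalog, fixture_catalog_path
from phenokit.records import PatientRecord, ProblemEntry, Status
from phenokit.simulate import default_concept_sets

INDEX = date(2005, 1, 1)


@pytest.fixture(scope="session")
def catalog():
    return load_term_catalog(fixture_catalog_path())


@pytest.fixture(scope="session")
def concept_sets(catalog):
    _, sets = default_concept_sets(catalog)
    return sets


@pytest.fixture(scope="session")
def cavd_set(concept_sets) -> ConceptSet:
    return concept_sets[Disease.CAVD]


@pytest.fixture(scope="session")
def cevd_set(concept_sets) -> ConceptSet:
    return concept_sets[Disease.CEVD]


def make_patient(
    pid: str = "p1",
    birth: date = date(1945, 6, 15),
    start: date = date(1999, 1, 1),
    end: date | None = None,
    encounters: tuple[date, ...] = (date(2003, 5, 1),),
    problems: tuple[ProblemEntry, ...] = (),
) -> PatientRecord:
    p = PatientRecord(
        patient_id=pid,
        birth_date=birth,
        enrollment_start=start,
        enrollment_end=end,
        encounter_dates=list(encounters),
        problems=list(problems),
    )
    p.validate()
    return p


def entry(
    vocab: str,
    code: str,
    status: Status = Status.ACTIVE,
    when: date = date(2003, 1, 1),
) -> ProblemEntry:
    return ProblemEntry(code=code, vocabulary=vocab, status=status, recorded_date=when)
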