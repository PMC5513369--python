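"""Patient-level EMR data model and serialization.

Cohorts are exchanged as JSONL, one patient object per line; gold-standard
chart-review labels as CSV.  All invariants on the types are checked at
read time, with line numbers in error messages, so downstream stages can
assume valid input.

The source system models each problem-list entry with a status flag —
``active`` (current confirmed problem), ``passive`` (confirmed but not
requiring intervention) or ``error`` (a code later judged false).  Status
is carried per entry; a correction is represented as the entry's final
status.  Free-text clinical notes are *not* modelled: a chart-positive
patient whose event lives only in narrative text appears here as a gold
label with mechanism ``freetext_only`` and no corresponding code.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .concepts import Disease

SCHEMA_VERSION = 1


class Status(str, Enum):
    ACTIVE = "active"
    PASSIVE = "passive"
    ERROR = "error"


class Setting(str, Enum):
    OUTPATIENT = "outpatient"
    INPATIENT = "inpatient"
    EMERGENCY = "emergency"
    HOME_CARE = "home-care"


class Mechanism(str, Enum):
    """Why a coded call and the chart truth diverge for a patient-disease pair.

    False-positive mechanisms (code present, chart negative):
    ``dismissed_diagnosis``, ``incidental_no_relevance``,
    ``code_without_note``, ``incorrect_abbreviation``.
    False-negative mechanisms (chart positive, no qualifying code):
    ``code_not_in_set``, ``freetext_only``, ``code_not_detected``,
    ``erroneous_date``.  ``none`` marks concordant pairs.
    """

    DISMISSED_DIAGNOSIS = "dismissed_diagnosis"
    INCIDENTAL_NO_RELEVANCE = "incidental_no_relevance"
    CODE_WITHOUT_NOTE = "code_without_note"
    INCORRECT_ABBREVIATION = "incorrect_abbreviation"
    CODE_NOT_IN_SET = "code_not_in_set"
    FREETEXT_ONLY = "freetext_only"
    CODE_NOT_DETECTED = "code_not_detected"
    ERRONEOUS_DATE = "erroneous_date"
    NONE = "none"


FP_MECHANISMS = frozenset(
    {
        Mechanism.DISMISSED_DIAGNOSIS,
        Mechanism.INCIDENTAL_NO_RELEVANCE,
        Mechanism.CODE_WITHOUT_NOTE,
        Mechanism.INCORRECT_ABBREVIATION,
    }
)
FN_MECHANISMS = frozenset(
    {
        Mechanism.CODE_NOT_IN_SET,
        Mechanism.FREETEXT_ONLY,
        Mechanism.CODE_NOT_DETECTED,
        Mechanism.ERRONEOUS_DATE,
    }
)


class ProblemType(str, Enum):
    """Clinical problem behind a discordant pair (taxonomy axis two)."""

    PVD = "PVD"                    # peripheral vascular disease
    CHF = "CHF"                    # heart failure
    MI = "MI"                      # acute myocardial infarction
    CAVD_SYMPTOM = "cavd_symptom"  # chest pain, angina, chest oppression
    STROKE = "stroke"
    TIA = "TIA"
    NONE = "none"


class RecordError(ValueError):
    """Invalid EMR record or gold-label input."""


@dataclass(frozen=True)
class ProblemEntry:
    code: str
    vocabulary: str
    status: Status
    recorded_date: date
    setting: Setting = Setting.OUTPATIENT

    @property
    def key(self) -> tuple[str, str]:
        return (self.vocabulary, self.code)


@dataclass
class PatientRecord:
    patient_id: str
    birth_date: date
    enrollment_start: date
    enrollment_end: date | None  # None = open-ended enrollment
    encounter_dates: list[date] = field(default_factory=list)
    problems: list[ProblemEntry] = field(default_factory=list)

    def validate(self) -> None:
        if self.enrollment_end is not None and self.enrollment_end < self.enrollment_start:
            raise RecordError(
                f"patient {self.patient_id}: enrollment_end {self.enrollment_end} "
                f"precedes enrollment_start {self.enrollment_start}"
            )
        for d in self.encounter_dates:
            if d < self.birth_date:
                raise RecordError(
                    f"patient {self.patient_id}: encounter date {d} precedes birth"
                )
        for p in self.problems:
            # pre-index history codes are legitimate; the only hard floor is birth
            if p.recorded_date < self.birth_date:
                raise RecordError(
                    f"patient {self.patient_id}: problem {p.key} recorded {p.recorded_date} "
                    "precedes birth"
                )


@dataclass(frozen=True)
class GoldLabel:
    """Chart-review truth for one (patient, disease) pair."""

    patient_id: str
    disease: Disease
    truth: bool
    mechanism: Mechanism = Mechanism.NONE
    problem_type: ProblemType = ProblemType.NONE


# ---------------------------------------------------------------------------
# JSONL cohort serialization


def _date_out(d: date | None) -> str | None:
    return None if d is None else d.isoformat()


def _date_in(s: str | None, context: str) -> date | None:
    if s is None:
        return None
    try:
        return date.fromisoformat(s)
    except ValueError as exc:
        raise RecordError(f"{context}: invalid date {s!r}") from exc


def patient_to_dict(p: PatientRecord) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "patient_id": p.patient_id,
        "birth_date": _date_out(p.birth_date),
        "enrollment_start": _date_out(p.enrollment_start),
        "enrollment_end": _date_out(p.enrollment_end),
        "encounter_dates": [d.isoformat() for d in p.encounter_dates],
        "problems": [
            {
                "code": e.code,
                "vocabulary": e.vocabulary,
                "status": e.status.value,
                "recorded_date": e.recorded_date.isoformat(),
                "setting": e.setting.value,
            }
            for e in p.problems
        ],
    }


def patient_from_dict(obj: dict, context: str = "record") -> PatientRecord:
    try:
        problems = []
        for i, e in enumerate(obj.get("problems", [])):
            try:
                status = Status(e["status"])
            except ValueError as exc:
                raise RecordError(
                    f"{context}: problem {i}: invalid status {e['status']!r} "
                    f"(expected one of {[s.value for s in Status]})"
                ) from exc
            problems.append(
                ProblemEntry(
                    code=e["code"],
                    vocabulary=e["vocabulary"],
                    status=status,
                    recorded_date=_date_in(e["recorded_date"], context),
                    setting=Setting(e.get("setting", "outpatient")),
                )
            )
        patient = PatientRecord(
            patient_id=str(obj["patient_id"]),
            birth_date=_date_in(obj["birth_date"], context),
            enrollment_start=_date_in(obj["enrollment_start"], context),
            enrollment_end=_date_in(obj.get("enrollment_end"), context),
            encounter_dates=[_date_in(d, context) for d in obj.get("encounter_dates", [])],
            problems=problems,
        )
    except KeyError as exc:
        raise RecordError(f"{context}: missing field {exc.args[0]!r}") from exc
    patient.validate()
    return patient


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a JSONL cohort, validating every record."""
    path = Path(path)
    cohort: list[PatientRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise RecordError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            patient = patient_from_dict(obj, context=f"{path}:{lineno}")
            if patient.patient_id in seen:
                raise RecordError(f"{path}:{lineno}: duplicate patient_id {patient.patient_id}")
            seen.add(patient.patient_id)
            cohort.append(patient)
    return cohort


def write_cohort(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort as JSONL; ``read_cohort`` round-trips it losslessly."""
    with open(path, "w") as fh:
        for p in cohort:
            fh.write(json.dumps(patient_to_dict(p), sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Gold labels (CSV)

GOLD_COLUMNS = ["patient_id", "disease", "truth", "mechanism", "problem_type"]


def read_gold_labels(path: str | Path) -> list[GoldLabel]:
    """Read gold-standard labels; at most one label per (patient, disease)."""
    path = Path(path)
    labels: list[GoldLabel] = []
    seen: set[tuple[str, str]] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = {"patient_id", "disease", "truth"} - set(reader.fieldnames or [])
        if missing:
            raise RecordError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            key = (row["patient_id"], row["disease"])
            if key in seen:
                raise RecordError(f"{path}:{lineno}: duplicate label for {key}")
            seen.add(key)
            truth_raw = row["truth"].strip().lower()
            if truth_raw not in {"true", "false", "1", "0"}:
                raise RecordError(f"{path}:{lineno}: invalid truth value {row['truth']!r}")
            mech_raw = (row.get("mechanism") or "").strip()
            try:
                mechanism = Mechanism(mech_raw) if mech_raw else Mechanism.NONE
            except ValueError as exc:
                raise RecordError(
                    f"{path}:{lineno}: unknown mechanism {mech_raw!r}"
                ) from exc
            pt_raw = (row.get("problem_type") or "").strip()
            problem_type = ProblemType(pt_raw) if pt_raw else ProblemType.NONE
            labels.append(
                GoldLabel(
                    patient_id=row["patient_id"],
                    disease=Disease(row["disease"]),
                    truth=truth_raw in {"true", "1"},
                    mechanism=mechanism,
                    problem_type=problem_type,
                )
            )
    return labels


def write_gold_labels(labels: Iterable[GoldLabel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(GOLD_COLUMNS)
        for g in labels:
            writer.writerow(
                [
                    g.patient_id,
                    g.disease.value,
                    "true" if g.truth else "false",
                    g.mechanism.value if g.mechanism is not Mechanism.NONE else "",
                    g.problem_type.value if g.problem_type is not ProblemType.NONE else "",
                ]
            )
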