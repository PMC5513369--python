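"""The case-detection algorithm: eligibility, per-disease calls, groups, sampling.

The rule is deliberately parsimonious: a patient is positive for a disease
if the problem list contains at least one concept-set code recorded before
the index date whose status is not ``error``; otherwise negative.  The two
per-disease calls place every patient in one of four groups (negative /
CaVD-only / CeVD-only / both), from which the validation sample is drawn
with roughly equal strata to enrich for positives.

Temporal convention: the observation window is half-open ``[-inf,
index_date)`` — a code dated on the index date does not count.  Age is
completed years at the index date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np

from .concepts import ConceptSet, Disease
from .records import PatientRecord, Status

logger = logging.getLogger(__name__)

DEFAULT_INDEX_DATE = date(2005, 1, 1)


@dataclass(frozen=True)
class EligibilityRule:
    """Inclusion criteria assessed at the index date.

    Defaults mirror a typical HMO validation design: ages 40-79 (completed
    years), at least one year of continuous enrollment ("seniority")
    immediately before the index date with enrollment still active at
    index, and at least one clinical encounter before index.
    """

    index_date: date = DEFAULT_INDEX_DATE
    min_age_years: int = 40
    max_age_years: int = 79
    min_enrollment_years: float = 1.0
    min_encounters: int = 1

    def __post_init__(self) -> None:
        if self.min_age_years > self.max_age_years:
            raise ValueError("min_age_years must not exceed max_age_years")
        if self.min_enrollment_years <= 0:
            raise ValueError("min_enrollment_years must be positive")


@dataclass(frozen=True)
class EligibilityResult:
    eligible: bool
    reasons: tuple[str, ...] = ()  # failed criteria: age, seniority, encounters

    def __bool__(self) -> bool:
        return self.eligible


@dataclass(frozen=True)
class PhenotypeCall:
    """The algorithm's verdict for one (patient, disease) pair."""

    patient_id: str
    disease: Disease
    positive: bool
    triggering_codes: tuple[tuple[str, str, date], ...] = ()

    def __post_init__(self) -> None:
        if self.positive != bool(self.triggering_codes):
            raise ValueError(
                f"patient {self.patient_id}: positive={self.positive} inconsistent "
                f"with {len(self.triggering_codes)} triggering codes"
            )


@dataclass(frozen=True)
class GroupAssignment:
    patient_id: str
    group: int  # 1=negative, 2=CaVD-only, 3=CeVD-only, 4=both


GROUP_LABELS = {
    1: "both absent",
    2: "CaVD only",
    3: "CeVD only",
    4: "both present",
}


def completed_age_years(birth_date: date, at: date) -> int:
    """Age in completed (birthday-based) years."""
    years = at.year - birth_date.year
    if (at.month, at.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def _years_before(d: date, years: float) -> date:
    whole = int(years)
    frac_days = round((years - whole) * 365.25)
    try:
        shifted = d.replace(year=d.year - whole)
    except ValueError:  # Feb 29
        shifted = d.replace(year=d.year - whole, day=28)
    return shifted - timedelta(days=frac_days)


def is_eligible(patient: PatientRecord, rule: EligibilityRule) -> EligibilityResult:
    """Assess the inclusion criteria; failures carry the failed criterion."""
    reasons: list[str] = []
    age = completed_age_years(patient.birth_date, rule.index_date)
    if not (rule.min_age_years <= age <= rule.max_age_years):
        reasons.append("age")
    seniority_cutoff = _years_before(rule.index_date, rule.min_enrollment_years)
    active_at_index = (
        patient.enrollment_end is None or patient.enrollment_end >= rule.index_date
    )
    if patient.enrollment_start > seniority_cutoff or not active_at_index:
        reasons.append("seniority")
    n_prior = sum(1 for d in patient.encounter_dates if d < rule.index_date)
    if n_prior < rule.min_encounters:
        reasons.append("encounters")
    return EligibilityResult(eligible=not reasons, reasons=tuple(reasons))


def classify_patient(
    patient: PatientRecord, concept_set: ConceptSet, index_date: date
) -> PhenotypeCall:
    """Apply the detection rule for one disease.

    Positive iff some problem entry carries an included ``(vocabulary,
    code)``, has status active or passive, and is recorded strictly before
    the index date.  Entries with status ``error`` never contribute — but
    they never veto a distinct qualifying entry either.  All qualifying
    entries are listed as triggering codes.
    """
    triggers = tuple(
        (e.vocabulary, e.code, e.recorded_date)
        for e in patient.problems
        if e.status is not Status.ERROR
        and e.recorded_date < index_date
        and e.key in concept_set.included_codes
    )
    return PhenotypeCall(
        patient_id=patient.patient_id,
        disease=concept_set.disease,
        positive=bool(triggers),
        triggering_codes=triggers,
    )


def assign_group(call_cavd: PhenotypeCall, call_cevd: PhenotypeCall) -> GroupAssignment:
    """Combine the two per-disease calls into the four-group stratum."""
    if call_cavd.patient_id != call_cevd.patient_id:
        raise ValueError(
            f"mismatched patients: {call_cavd.patient_id} vs {call_cevd.patient_id}"
        )
    if call_cavd.disease is not Disease.CAVD or call_cevd.disease is not Disease.CEVD:
        raise ValueError("assign_group expects (CaVD call, CeVD call) in that order")
    table = {(False, False): 1, (True, False): 2, (False, True): 3, (True, True): 4}
    return GroupAssignment(
        patient_id=call_cavd.patient_id,
        group=table[(call_cavd.positive, call_cevd.positive)],
    )


def classify_cohort(
    cohort: Sequence[PatientRecord],
    concepts_cavd: ConceptSet,
    concepts_cevd: ConceptSet,
    index_date: date,
) -> tuple[list[PhenotypeCall], list[GroupAssignment]]:
    """Run both disease classifiers over a cohort and group every patient."""
    calls: list[PhenotypeCall] = []
    groups: list[GroupAssignment] = []
    for patient in cohort:
        ca = classify_patient(patient, concepts_cavd, index_date)
        ce = classify_patient(patient, concepts_cevd, index_date)
        calls.extend([ca, ce])
        groups.append(assign_group(ca, ce))
    return calls, groups


@dataclass
class SampleSummary:
    """Per-stratum counts of a stratified validation sample."""

    rows: list[dict] = field(default_factory=list)  # group, label, group_size, sampled_n, percent

    @property
    def total_sampled(self) -> int:
        return sum(r["sampled_n"] for r in self.rows)


def stratified_sample(
    groups: Mapping[int, Sequence[str]],
    per_stratum: int = 300,
    seed: int = 0,
) -> tuple[dict[int, list[str]], SampleSummary]:
    """Draw up to ``per_stratum`` patients per group, uniformly without replacement.

    Designed so each of the four algorithm-defined groups contributes
    roughly 25% of the review sample; a group smaller than the quota is
    taken whole with a logged warning, producing unequal strata.  The draw
    is a pure function of (sorted input, seed).
    """
    if per_stratum < 0:
        raise ValueError("per_stratum must be non-negative")
    from .validation import percent  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    sampled: dict[int, list[str]] = {}
    for group in sorted(groups):
        ids = sorted(groups[group])
        take = min(per_stratum, len(ids))
        if take < per_stratum:
            logger.warning(
                "stratum %d has only %d patients (< quota %d); taking all",
                group, len(ids), per_stratum,
            )
        picked = rng.choice(len(ids), size=take, replace=False)
        sampled[group] = [ids[i] for i in sorted(picked)]
    total = sum(len(v) for v in sampled.values())
    summary = SampleSummary(
        rows=[
            {
                "group": g,
                "label": GROUP_LABELS.get(g, str(g)),
                "group_size": len(groups[g]),
                "sampled_n": len(sampled[g]),
                "percent": percent(len(sampled[g]), total) if total else 0.0,
            }
            for g in sorted(sampled)
        ]
    )
    return sampled, summary


def strata_table(counts: Mapping[int, int]) -> list[dict]:
    """n (%) summary of final strata counts (denominator = their sum)."""
    from .validation import percent

    total = sum(counts.values())
    if total <= 0:
        raise ValueError("strata_table requires a positive total")
    return [
        {
            "group": g,
            "label": GROUP_LABELS.get(g, str(g)),
            "n": counts[g],
            "percent": percent(counts[g], total),
        }
        for g in sorted(counts)
    ]


@dataclass(frozen=True)
class FlowSummary:
    drawn: int
    ineligible: int

    @property
    def included(self) -> int:
        return self.drawn - self.ineligible

    def as_dict(self) -> dict:
        return {
            "drawn": self.drawn,
            "ineligible": self.ineligible,
            "included": self.included,
        }

    def render(self) -> str:
        return (
            f"sampled patients: {self.drawn}\n"
            f"  -> excluded (inclusion criteria not met): {self.ineligible}\n"
            f"  -> included in final analysis: {self.included}\n"
        )


def flow_summary(drawn: int, ineligible: int) -> FlowSummary:
    """Study-flow arithmetic: included = drawn - ineligible."""
    if ineligible > drawn:
        raise ValueError(f"ineligible ({ineligible}) exceeds drawn ({drawn})")
    if drawn < 0 or ineligible < 0:
        raise ValueError("counts must be non-negative")
    return FlowSummary(drawn=drawn, ineligible=ineligible)
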