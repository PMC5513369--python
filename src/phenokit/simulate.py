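"""Synthetic EMR cohorts with known truth and planted coding errors.

Real validation of a phenotyping rule needs charts; this module builds the
next best thing for testing the machinery: a cohort in which every
(patient, disease) pair has a known gold label and, for a configurable
minority, a *planted* discordance mechanism drawn from those observed when
coded problem lists are audited against charts:

* false-positive mechanisms (code fires, chart says no): a dismissed
  diagnosis whose code was never set to ``error``, an incidental finding
  without clinical relevance, a code with no correlate in the notes, a
  misused abbreviation;
* false-negative mechanisms (chart says yes, rule misses): the relevant
  code lies outside the concept set, the event exists only in free text,
  or the only qualifying code carries an erroneous (post-index) date.

Each pair receives at most one mechanism.  Mechanism rates are absolute
per-pair probabilities carved out of the prevalence mass, so the expected
sensitivity and specificity of the detection rule have closed forms
(:func:`expected_operating_characteristics`) against which a pipeline run
can be checked.

Randomness: each patient gets an independent generator seeded by
``(seed, patient_index)``, so growing the cohort never reshuffles earlier
patients and identical configs reproduce byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .concepts import (
    ConceptSet,
    Disease,
    DiseaseDomain,
    TermEntry,
    fixture_catalog_path,
    load_term_catalog,
    merge_reviewer_selections,
    select_terms,
)
from .records import (
    FN_MECHANISMS,
    FP_MECHANISMS,
    GoldLabel,
    Mechanism,
    PatientRecord,
    ProblemEntry,
    ProblemType,
    Setting,
    Status,
)

# Keywords used to build the default demo concept sets from the bundled
# catalog.  Local shorthand terms in the catalog deliberately evade these,
# providing the out-of-set code pool for the code_not_in_set mechanism.
CAVD_KEYWORDS = [
    "myocardial infarction", "angina", "heart failure", "chest", "coronary",
    "peripheral vascular", "claudication", "aneurysm", "atherosclero",
    "ischemi", "cardiac arrest",
]
CEVD_KEYWORDS = [
    "stroke", "cerebral", "cerebrovascular", "transient ischemic", "carotid",
    "hemiparesis", "intracranial", "endarterectomy",
]

# Default per-pair mechanism probabilities.  They echo the error composition
# observed in published problem-list audits: dismissed diagnoses dominate
# cardiovascular false positives, incidental imaging findings dominate
# cerebrovascular ones, and missing/out-of-set codes dominate the (rarer)
# false negatives.
DEFAULT_MECHANISM_RATES: dict[Disease, dict[Mechanism, float]] = {
    Disease.CAVD: {
        Mechanism.CODE_NOT_IN_SET: 0.0145,
        Mechanism.FREETEXT_ONLY: 0.0045,
        Mechanism.ERRONEOUS_DATE: 0.0,
        Mechanism.DISMISSED_DIAGNOSIS: 0.0298,
        Mechanism.INCIDENTAL_NO_RELEVANCE: 0.0,
        Mechanism.CODE_WITHOUT_NOTE: 0.0036,
        Mechanism.INCORRECT_ABBREVIATION: 0.0018,
    },
    Disease.CEVD: {
        Mechanism.CODE_NOT_IN_SET: 0.0054,
        Mechanism.FREETEXT_ONLY: 0.0036,
        Mechanism.ERRONEOUS_DATE: 0.0009,
        Mechanism.DISMISSED_DIAGNOSIS: 0.0090,
        Mechanism.INCIDENTAL_NO_RELEVANCE: 0.0118,
        Mechanism.CODE_WITHOUT_NOTE: 0.0036,
        Mechanism.INCORRECT_ABBREVIATION: 0.0,
    },
}

# Clinical problems behind planted discordances, per disease.
DEFAULT_PROBLEM_TYPE_MIX: dict[Disease, dict[ProblemType, float]] = {
    Disease.CAVD: {
        ProblemType.PVD: 0.29,
        ProblemType.CHF: 0.18,
        ProblemType.MI: 0.18,
        ProblemType.CAVD_SYMPTOM: 0.35,
    },
    Disease.CEVD: {
        ProblemType.STROKE: 0.80,
        ProblemType.TIA: 0.20,
    },
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort.

    ``prevalence`` is the marginal chart-truth probability per disease;
    ``mechanism_rates`` are absolute per-pair probabilities (false-negative
    mechanisms are carved out of the prevalence mass, false-positive
    mechanisms out of its complement, so feasibility requires
    sum(FN rates) <= prevalence and sum(FP rates) <= 1 - prevalence).
    """

    n_patients: int = 1200
    index_date: date = date(2005, 1, 1)
    age_range: tuple[int, int] = (40, 79)
    prevalence: dict[Disease, float] = field(
        default_factory=lambda: {Disease.CAVD: 0.12, Disease.CEVD: 0.08}
    )
    mechanism_rates: dict[Disease, dict[Mechanism, float]] = field(
        default_factory=lambda: {
            d: dict(v) for d, v in DEFAULT_MECHANISM_RATES.items()
        }
    )
    problem_type_mix: dict[Disease, dict[ProblemType, float]] = field(
        default_factory=lambda: {
            d: dict(v) for d, v in DEFAULT_PROBLEM_TYPE_MIX.items()
        }
    )
    ineligible_fraction: float = 0.027
    encounter_mean: float = 6.0
    distractor_mean: float = 2.0
    # fraction of concordant-negative pairs that carry an in-set code whose
    # status was correctly set to error (exercises the error-status rule)
    corrected_error_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for frac_name in ("ineligible_fraction", "corrected_error_rate"):
            v = getattr(self, frac_name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{frac_name} must be in [0,1], got {v}")
        for d in Disease:
            prev = self.prevalence.get(d, 0.0)
            if not 0 <= prev <= 1:
                raise SimulationError(f"prevalence[{d.value}] out of [0,1]")
            rates = self.mechanism_rates.get(d, {})
            for m, r in rates.items():
                if r < 0 or r > 1:
                    raise SimulationError(f"rate {m.value} out of [0,1]")
                if r > 0 and m not in FP_MECHANISMS | FN_MECHANISMS:
                    raise SimulationError(f"{m.value} is not a plantable mechanism")
            fn_mass = sum(r for m, r in rates.items() if m in FN_MECHANISMS)
            fp_mass = sum(r for m, r in rates.items() if m in FP_MECHANISMS)
            if fn_mass > prev + 1e-12:
                raise SimulationError(
                    f"{d.value}: FN-mechanism mass {fn_mass:.4f} exceeds prevalence {prev}"
                )
            if fp_mass > 1 - prev + 1e-12:
                raise SimulationError(
                    f"{d.value}: FP-mechanism mass {fp_mass:.4f} exceeds 1 - prevalence"
                )
            mix = self.problem_type_mix.get(d, {})
            if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise SimulationError(f"problem_type_mix[{d.value}] must sum to 1")
        if self.age_range[0] > self.age_range[1]:
            raise SimulationError("age_range must be (low, high)")


def default_concept_sets(
    catalog: list[TermEntry] | None = None,
) -> tuple[list[TermEntry], dict[Disease, ConceptSet]]:
    """Catalog plus keyword-built concept sets used by the demo pipeline."""
    if catalog is None:
        catalog = load_term_catalog(fixture_catalog_path())
    # agreed carve-out: incidental imaging findings without clinical relevance
    incidental = {("snomed", "445038001")}
    sets = {
        Disease.CAVD: merge_reviewer_selections(
            [select_terms(catalog, CAVD_KEYWORDS, Disease.CAVD, name="reviewer-panel")],
            exclusions=incidental,
        ),
        Disease.CEVD: merge_reviewer_selections(
            [select_terms(catalog, CEVD_KEYWORDS, Disease.CEVD, name="reviewer-panel")]
        ),
    }
    return catalog, sets


@dataclass
class SimulatedCohort:
    cohort: list[PatientRecord]
    gold: list[GoldLabel]
    manifest: pd.DataFrame  # patient_id, disease, eligible, gold, expected_call, mechanism, problem_type
    concept_sets: dict[Disease, ConceptSet]
    config: SimulationConfig


_CONCORDANT_POS = "concordant_positive"
_CONCORDANT_NEG = "concordant_negative"


def _pair_categories(config: SimulationConfig, disease: Disease):
    """Category labels and probabilities of one patient-disease pair."""
    prev = config.prevalence.get(disease, 0.0)
    rates = config.mechanism_rates.get(disease, {})
    fn = [(m, rates.get(m, 0.0)) for m in sorted(FN_MECHANISMS, key=lambda m: m.value)]
    fp = [(m, rates.get(m, 0.0)) for m in sorted(FP_MECHANISMS, key=lambda m: m.value)]
    fn_mass = sum(r for _, r in fn)
    fp_mass = sum(r for _, r in fp)
    labels = [_CONCORDANT_POS] + [m.value for m, _ in fn] + [m.value for m, _ in fp] + [_CONCORDANT_NEG]
    probs = np.asarray(
        [prev - fn_mass]
        + [r for _, r in fn]
        + [r for _, r in fp]
        + [1 - prev - fp_mass],
        dtype=float,
    )
    probs = np.clip(probs, 0.0, None)
    return labels, probs / probs.sum()


def _category_outcome(label: str) -> tuple[bool, bool]:
    """(gold truth, expected algorithm call) for a pair category."""
    if label == _CONCORDANT_POS:
        return True, True
    if label == _CONCORDANT_NEG:
        return False, False
    m = Mechanism(label)
    if m in FN_MECHANISMS:
        return True, False
    return False, True


def _rand_date(rng: np.random.Generator, lo: date, hi: date) -> date:
    """Uniform date in [lo, hi)."""
    span = (hi - lo).days
    return lo + timedelta(days=int(rng.integers(0, max(span, 1))))


def _pick(rng: np.random.Generator, pool: list[tuple[str, str]]) -> tuple[str, str]:
    return pool[int(rng.integers(0, len(pool)))]


def generate_cohort(
    config: SimulationConfig,
    catalog: list[TermEntry] | None = None,
    concept_sets: dict[Disease, ConceptSet] | None = None,
) -> SimulatedCohort:
    """Build a synthetic cohort with known labels and planted mechanisms.

    Generative rules per eligible (patient, disease) pair:

    * concordant positive — one or two in-set codes, active/passive,
      recorded before index;
    * concordant negative — no in-set non-error codes (a small fraction
      gets an in-set code correctly statused ``error``);
    * FP mechanisms — an in-set active code before index on a
      chart-negative patient;
    * ``code_not_in_set`` — chart-positive, only disease-relevant codes
      *outside* the concept set;
    * ``freetext_only`` — chart-positive, no codes at all;
    * ``erroneous_date`` — chart-positive, the only in-set code is dated
      on/after index.

    Distractor codes (disease domain ``none``) are sprinkled on everyone;
    a configured fraction of patients violates an eligibility criterion.
    """
    config.validate()
    if catalog is None or concept_sets is None:
        catalog, default_sets = default_concept_sets(catalog)
        concept_sets = concept_sets or default_sets

    # planting pools are kept disjoint across diseases so a code planted for
    # one disease can never accidentally trigger the other's call
    other = {Disease.CAVD: Disease.CEVD, Disease.CEVD: Disease.CAVD}
    any_set = {k for cs in concept_sets.values() for k in cs.included_codes}
    in_set = {
        d: sorted(concept_sets[d].included_codes - concept_sets[other[d]].included_codes)
        for d in Disease
    }
    out_set = {
        d: sorted(
            e.key
            for e in catalog
            if e.disease_domain in (DiseaseDomain(d.value), DiseaseDomain.BOTH)
            and e.key not in any_set
        )
        for d in Disease
    }
    distractors = sorted(e.key for e in catalog if e.disease_domain is DiseaseDomain.NONE)
    for d in Disease:
        if not in_set[d]:
            raise SimulationError(f"empty concept set for {d.value}")
        needs_out = config.mechanism_rates.get(d, {}).get(Mechanism.CODE_NOT_IN_SET, 0) > 0
        if needs_out and not out_set[d]:
            raise SimulationError(f"no out-of-set codes available for {d.value}")

    index = config.index_date
    lo_age, hi_age = config.age_range
    patients: list[PatientRecord] = []
    gold: list[GoldLabel] = []
    manifest_rows: list[dict] = []

    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        pid = f"P{i:05d}"
        violation = None
        if rng.random() < config.ineligible_fraction:
            violation = ["age_low", "age_high", "seniority", "encounters"][
                int(rng.integers(0, 4))
            ]

        if violation == "age_low":
            age = rng.uniform(25, lo_age - 0.1)
        elif violation == "age_high":
            age = rng.uniform(hi_age + 1.2, hi_age + 15)
        else:
            age = rng.uniform(lo_age + 0.05, hi_age + 0.95)
        birth = index - timedelta(days=int(age * 365.25))

        if violation == "seniority":
            start = index - timedelta(days=int(rng.integers(10, 360)))
        else:
            start = index - timedelta(days=int(rng.integers(400, 3650)))
        end = None if rng.random() < 0.9 else index + timedelta(days=int(rng.integers(0, 1000)))

        if violation == "encounters":
            encounters: list[date] = []
        else:
            n_enc = 1 + int(rng.poisson(max(config.encounter_mean - 1, 0)))
            enc_lo = max(start, index - timedelta(days=3650))
            encounters = sorted(_rand_date(rng, enc_lo, index) for _ in range(n_enc))

        problems: list[ProblemEntry] = []
        hist_lo = index - timedelta(days=3650)

        def add(code_key: tuple[str, str], status: Status, when: date) -> None:
            problems.append(
                ProblemEntry(
                    code=code_key[1],
                    vocabulary=code_key[0],
                    status=status,
                    recorded_date=when,
                    setting=list(Setting)[int(rng.integers(0, 4))],
                )
            )

        for d in Disease:
            labels, probs = _pair_categories(config, d)
            if violation is None:
                cat = labels[int(rng.choice(len(labels), p=probs))]
            else:
                # ineligible patients stay concordant; mechanisms are planted
                # only on the analysable population
                cat = _CONCORDANT_POS if rng.random() < config.prevalence.get(d, 0.0) else _CONCORDANT_NEG
            truth, expected = _category_outcome(cat)
            mechanism = Mechanism.NONE if cat in (_CONCORDANT_POS, _CONCORDANT_NEG) else Mechanism(cat)
            if mechanism is Mechanism.NONE:
                problem_type = ProblemType.NONE
            else:
                mix = config.problem_type_mix.get(d, {})
                pts = sorted(mix, key=lambda p: p.value)
                if pts:
                    w = np.asarray([mix[p] for p in pts], dtype=float)
                    problem_type = pts[int(rng.choice(len(pts), p=w / w.sum()))]
                else:
                    problem_type = ProblemType.NONE

            if cat == _CONCORDANT_POS:
                for _ in range(1 + int(rng.random() < 0.4)):
                    status = Status.PASSIVE if rng.random() < 0.3 else Status.ACTIVE
                    add(_pick(rng, in_set[d]), status, _rand_date(rng, hist_lo, index))
            elif cat == _CONCORDANT_NEG:
                if rng.random() < config.corrected_error_rate:
                    add(_pick(rng, in_set[d]), Status.ERROR, _rand_date(rng, hist_lo, index))
            elif mechanism in FP_MECHANISMS:
                add(_pick(rng, in_set[d]), Status.ACTIVE, _rand_date(rng, hist_lo, index))
            elif mechanism is Mechanism.CODE_NOT_IN_SET:
                add(_pick(rng, out_set[d]), Status.ACTIVE, _rand_date(rng, hist_lo, index))
            elif mechanism is Mechanism.ERRONEOUS_DATE:
                add(
                    _pick(rng, in_set[d]),
                    Status.ACTIVE,
                    index + timedelta(days=int(rng.integers(1, 365))),
                )
            # freetext_only: chart-positive with no codes

            gold.append(
                GoldLabel(
                    patient_id=pid,
                    disease=d,
                    truth=truth,
                    mechanism=mechanism,
                    problem_type=problem_type,
                )
            )
            manifest_rows.append(
                {
                    "patient_id": pid,
                    "disease": d.value,
                    "eligible": violation is None,
                    "violation": violation or "",
                    "gold": truth,
                    "expected_call": expected,
                    "mechanism": mechanism.value,
                    "problem_type": problem_type.value,
                }
            )

        if distractors:
            for _ in range(int(rng.poisson(config.distractor_mean))):
                status = Status.PASSIVE if rng.random() < 0.3 else Status.ACTIVE
                add(_pick(rng, distractors), status, _rand_date(rng, hist_lo, index))

        problems.sort(key=lambda e: (e.recorded_date, e.vocabulary, e.code))
        patient = PatientRecord(
            patient_id=pid,
            birth_date=birth,
            enrollment_start=start,
            enrollment_end=end,
            encounter_dates=encounters,
            problems=problems,
        )
        patient.validate()
        patients.append(patient)

    manifest = pd.DataFrame(manifest_rows)
    return SimulatedCohort(
        cohort=patients,
        gold=gold,
        manifest=manifest,
        concept_sets=concept_sets,
        config=config,
    )


@dataclass(frozen=True)
class ExpectedOC:
    sensitivity: float | None
    specificity: float | None


def expected_operating_characteristics(
    config: SimulationConfig,
) -> dict[str, ExpectedOC]:
    """Closed-form expected sensitivity/specificity of the detection rule.

    Per disease: sensitivity = (prevalence - FN-mechanism mass)/prevalence,
    specificity = (1 - prevalence - FP-mechanism mass)/(1 - prevalence).
    The combined outcome (positive-if-either on both axes) is computed
    exactly by enumerating the joint pair categories of the two diseases,
    which are independent by construction.
    """
    config.validate()
    out: dict[str, ExpectedOC] = {}
    per_disease: dict[Disease, tuple[list[str], np.ndarray]] = {}
    for d in Disease:
        labels, probs = _pair_categories(config, d)
        per_disease[d] = (labels, probs)
        prev = config.prevalence.get(d, 0.0)
        fn_mass = sum(
            r for m, r in config.mechanism_rates.get(d, {}).items() if m in FN_MECHANISMS
        )
        fp_mass = sum(
            r for m, r in config.mechanism_rates.get(d, {}).items() if m in FP_MECHANISMS
        )
        sens = (prev - fn_mass) / prev if prev > 0 else None
        spec = (1 - prev - fp_mass) / (1 - prev) if prev < 1 else None
        out[d.value] = ExpectedOC(sensitivity=sens, specificity=spec)

    # combined outcome by exact enumeration of joint categories
    p_pos = p_tp = p_neg = p_tn = 0.0
    la, pa = per_disease[Disease.CAVD]
    lb, pb = per_disease[Disease.CEVD]
    for i, ca in enumerate(la):
        ga, ta = _category_outcome(ca)
        for j, cb in enumerate(lb):
            gb, tb = _category_outcome(cb)
            w = pa[i] * pb[j]
            gold_pos = ga or gb
            test_pos = ta or tb
            if gold_pos:
                p_pos += w
                p_tp += w * test_pos
            else:
                p_neg += w
                p_tn += w * (not test_pos)
    out["combined"] = ExpectedOC(
        sensitivity=p_tp / p_pos if p_pos > 0 else None,
        specificity=p_tn / p_neg if p_neg > 0 else None,
    )
    return out


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=seed)
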