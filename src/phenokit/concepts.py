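"""Disease concept sets (code lists) that define the phenotype.

A phenotype here is operationalised as a *concept set*: the collection of
coded terms — signs, symptoms, diagnoses and procedures — whose presence in
a patient's problem list marks the patient as a case.  Concept sets are
built by keyword selection against a terminology catalog, merged across
reviewers under a sensitivity-maximising union policy, and persisted as
plain CSV so that the exact code list behind any run is inspectable.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

CATALOG_COLUMNS = ["vocabulary", "code", "description", "category", "disease_domain"]
CONCEPT_SET_COLUMNS = CATALOG_COLUMNS + ["included", "provenance"]


class Vocabulary(str, Enum):
    """Source terminology of a coded term."""

    SNOMED = "snomed"        # SNOMED-CT-like concept identifiers
    ICD10 = "icd10"          # ICD-10-like codes
    ICPC2 = "icpc2"          # ICPC-2-like primary-care codes
    LOCAL = "local"          # hospital-specific, non-standardised terms


class Category(str, Enum):
    SIGN = "sign"
    SYMPTOM = "symptom"
    DIAGNOSIS = "diagnosis"
    PROCEDURE = "procedure"


class Disease(str, Enum):
    """The two phenotypes detected by the algorithm."""

    CAVD = "CaVD"  # cardiovascular disease
    CEVD = "CeVD"  # cerebrovascular disease


class DiseaseDomain(str, Enum):
    """Which phenotype(s) a catalog term is clinically associated with.

    ``NONE`` marks distractor terms that belong to no concept set (the
    catalog deliberately carries such terms so that selection has something
    to exclude).
    """

    CAVD = "CaVD"
    CEVD = "CeVD"
    BOTH = "both"
    NONE = "none"


class CatalogError(ValueError):
    """Malformed or inconsistent terminology input."""


@dataclass(frozen=True)
class TermEntry:
    """One coded clinical term in the terminology catalog."""

    code: str
    vocabulary: Vocabulary
    description: str
    category: Category
    disease_domain: DiseaseDomain

    def __post_init__(self) -> None:
        if not self.code:
            raise CatalogError("TermEntry.code must be non-empty")

    @property
    def key(self) -> tuple[str, str]:
        """(vocabulary, code) identity used throughout the pipeline."""
        return (self.vocabulary.value, self.code)


@dataclass
class ConceptSet:
    """The code list defining one disease phenotype.

    ``included_codes`` and ``excluded_codes`` are sets of
    ``(vocabulary, code)`` pairs; ``provenance`` records which reviewer
    selection(s) contributed each included code.
    """

    name: str
    disease: Disease
    included_codes: set[tuple[str, str]] = field(default_factory=set)
    excluded_codes: set[tuple[str, str]] = field(default_factory=set)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.included_codes & self.excluded_codes
        if overlap:
            raise CatalogError(
                f"concept set {self.name!r}: codes both included and excluded: {sorted(overlap)}"
            )

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.included_codes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConceptSet):
            return NotImplemented
        return (
            self.name == other.name
            and self.disease == other.disease
            and self.included_codes == other.included_codes
            and self.excluded_codes == other.excluded_codes
        )


def fixture_catalog_path() -> Path:
    """Path of the bundled mini terminology catalog.

    The catalog is a synthetic stand-in covering both diseases, every term
    category, non-standard local terms and distractor terms outside either
    phenotype; it exists so the whole pipeline is exercisable without
    licensed terminology content.
    """
    with resources.as_file(resources.files("phenokit.data") / "term_catalog.csv") as p:
        return Path(p)


def load_term_catalog(
    path: str | Path, vocabulary: Vocabulary | None = None
) -> list[TermEntry]:
    """Load a terminology catalog from CSV.

    The file must carry the header columns ``code, description, category,
    disease_domain`` and either a ``vocabulary`` column or a single
    ``vocabulary`` passed here applying to every row.  Duplicate
    ``(vocabulary, code)`` pairs are rejected with their row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"term catalog not found: {path}")
    entries: list[TermEntry] = []
    seen: dict[tuple[str, str], int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"code", "description", "category", "disease_domain"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise CatalogError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            code = (row.get("code") or "").strip()
            if not code:
                raise CatalogError(f"{path}:{lineno}: missing code")
            vocab_raw = (row.get("vocabulary") or "").strip()
            if vocab_raw:
                vocab = Vocabulary(vocab_raw)
            elif vocabulary is not None:
                vocab = vocabulary
            else:
                raise CatalogError(
                    f"{path}:{lineno}: no vocabulary column and no default vocabulary given"
                )
            entry = TermEntry(
                code=code,
                vocabulary=vocab,
                description=(row.get("description") or "").strip(),
                category=Category(row["category"].strip()),
                disease_domain=DiseaseDomain(row["disease_domain"].strip()),
            )
            if entry.key in seen:
                raise CatalogError(
                    f"{path}:{lineno}: duplicate code {entry.key} "
                    f"(first seen on line {seen[entry.key]})"
                )
            seen[entry.key] = lineno
            entries.append(entry)
    return entries


def select_terms(
    catalog: Sequence[TermEntry],
    keywords: Sequence[str],
    disease: Disease,
    name: str | None = None,
    provenance: str = "keyword-selection",
) -> ConceptSet:
    """Select catalog terms for one disease by keyword.

    Matching is case-insensitive substring match on the description.  A
    term is included when it matches at least one keyword *and* its disease
    domain is the requested disease or ``both``; category is never a filter
    (signs, symptoms, diagnoses and procedures are all eligible).  Terms
    outside the disease domain — including distractors with domain
    ``none`` — are never included.
    """
    if not keywords:
        raise CatalogError("select_terms requires at least one keyword")
    lowered = [k.lower() for k in keywords]
    wanted_domains = {DiseaseDomain(disease.value), DiseaseDomain.BOTH}
    cs = ConceptSet(name=name or f"{disease.value}-selection", disease=disease)
    for entry in catalog:
        if entry.disease_domain not in wanted_domains:
            continue
        desc = entry.description.lower()
        if any(k in desc for k in lowered):
            cs.included_codes.add(entry.key)
            cs.provenance[entry.key] = provenance
    if catalog and not cs.included_codes:
        logger.warning(
            "select_terms: no %s terms matched keywords %s", disease.value, list(keywords)
        )
    return cs


def merge_reviewer_selections(
    selections: Sequence[ConceptSet],
    exclusions: Iterable[tuple[str, str]] = (),
    name: str | None = None,
) -> ConceptSet:
    """Merge independent reviewer selections into the final concept set.

    Discrepancies between reviewers are resolved in favour of sensitivity:
    the merged set is the *union* of all selections, so a code kept by any
    one reviewer stays in.  ``exclusions`` models the one agreed carve-out —
    terms describing incidental findings without clinical relevance — and is
    removed after the union.  Provenance lists every contributing selection
    per code.
    """
    if not selections:
        raise CatalogError("merge_reviewer_selections requires at least one selection")
    diseases = {s.disease for s in selections}
    if len(diseases) > 1:
        raise CatalogError(
            f"cannot merge selections for different diseases: {sorted(d.value for d in diseases)}"
        )
    disease = selections[0].disease
    exclusions = set(exclusions)
    merged = ConceptSet(
        name=name or f"{disease.value}-merged",
        disease=disease,
        excluded_codes=set(exclusions),
    )
    for sel in selections:
        for key in sel.included_codes:
            if key in exclusions:
                continue
            merged.included_codes.add(key)
            prior = merged.provenance.get(key)
            tag = sel.name
            merged.provenance[key] = f"{prior}+{tag}" if prior else tag
    return merged


def validate_against_catalog(cs: ConceptSet, catalog: Sequence[TermEntry]) -> None:
    """Check that every included code exists in the catalog."""
    known = {e.key for e in catalog}
    unknown = cs.included_codes - known
    if unknown:
        raise CatalogError(
            f"concept set {cs.name!r} includes codes absent from the catalog: {sorted(unknown)}"
        )


def write_concept_set(
    cs: ConceptSet, catalog: Sequence[TermEntry], path: str | Path
) -> None:
    """Persist a concept set as CSV (one row per included/excluded code)."""
    by_key: Mapping[tuple[str, str], TermEntry] = {e.key: e for e in catalog}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "disease"] + CONCEPT_SET_COLUMNS)
        for key in sorted(cs.included_codes | cs.excluded_codes):
            entry = by_key.get(key)
            writer.writerow(
                [
                    cs.name,
                    cs.disease.value,
                    key[0],
                    key[1],
                    entry.description if entry else "",
                    entry.category.value if entry else "",
                    entry.disease_domain.value if entry else "",
                    "1" if key in cs.included_codes else "0",
                    cs.provenance.get(key, ""),
                ]
            )


def read_concept_set(path: str | Path) -> ConceptSet:
    """Load a concept set written by :func:`write_concept_set`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"concept set not found: {path}")
    cs: ConceptSet | None = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            if cs is None:
                cs = ConceptSet(name=row["name"], disease=Disease(row["disease"]))
            key = (row["vocabulary"], row["code"])
            if row["included"] == "1":
                cs.included_codes.add(key)
                if row.get("provenance"):
                    cs.provenance[key] = row["provenance"]
            else:
                cs.excluded_codes.add(key)
    if cs is None:
        raise CatalogError(f"{path}: empty concept-set file")
    return cs
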