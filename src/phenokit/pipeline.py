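"""End-to-end pipeline: generate/load -> classify -> sample -> validate -> report.

A run is driven by a single YAML config; every stage writes its artifact to
the output directory and the final report bundle collects the flow summary,
strata table, operating characteristics and error taxonomies together with
a provenance block (config hash, seeds, package version).  Identical config
and seeds produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .concepts import ConceptSet, Disease, read_concept_set, write_concept_set
from .phenotyper import (
    EligibilityRule,
    PhenotypeCall,
    classify_cohort,
    flow_summary,
    is_eligible,
    strata_table,
    stratified_sample,
)
from .records import (
    GoldLabel,
    PatientRecord,
    read_cohort,
    read_gold_labels,
    write_cohort,
    write_gold_labels,
)
from .simulate import (
    SimulationConfig,
    default_concept_sets,
    generate_cohort,
)
from .validation import (
    error_taxonomy,
    operating_characteristics,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    index_date: date = date(2005, 1, 1)
    eligibility: EligibilityRule | None = None
    ci_method: str = "wilson"
    ci_level: float = 0.95
    per_stratum: int = 300
    seeds: dict[str, int] = field(default_factory=lambda: {"simulate": 11, "sample": 17})
    simulate: SimulationConfig | None = None
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.eligibility is None:
            self.eligibility = EligibilityRule(index_date=self.index_date)

    def canonical(self) -> dict:
        """JSON-safe view of the effective config, used for hashing/echoing."""
        sim = None
        if self.simulate is not None:
            sim = {
                "n_patients": self.simulate.n_patients,
                "index_date": self.simulate.index_date.isoformat(),
                "age_range": list(self.simulate.age_range),
                "prevalence": {d.value: v for d, v in self.simulate.prevalence.items()},
                "mechanism_rates": {
                    d.value: {m.value: r for m, r in rates.items()}
                    for d, rates in self.simulate.mechanism_rates.items()
                },
                "problem_type_mix": {
                    d.value: {p.value: w for p, w in mix.items()}
                    for d, mix in self.simulate.problem_type_mix.items()
                },
                "ineligible_fraction": self.simulate.ineligible_fraction,
                "encounter_mean": self.simulate.encounter_mean,
                "distractor_mean": self.simulate.distractor_mean,
                "corrected_error_rate": self.simulate.corrected_error_rate,
                "seed": self.simulate.seed,
            }
        return {
            "index_date": self.index_date.isoformat(),
            "eligibility": {
                "min_age_years": self.eligibility.min_age_years,
                "max_age_years": self.eligibility.max_age_years,
                "min_enrollment_years": self.eligibility.min_enrollment_years,
                "min_encounters": self.eligibility.min_encounters,
            },
            "ci_method": self.ci_method,
            "ci_level": self.ci_level,
            "per_stratum": self.per_stratum,
            "seeds": dict(sorted(self.seeds.items())),
            "simulate": sim,
            "paths": dict(sorted(self.paths.items())),
        }

    def hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_date(value: Any) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


def load_run_config(path: str | Path) -> RunConfig:
    """Parse the YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    index_date = _as_date(raw.get("index_date", "2005-01-01"))
    elig_raw = raw.get("eligibility", {})
    eligibility = EligibilityRule(
        index_date=index_date,
        min_age_years=int(elig_raw.get("min_age_years", 40)),
        max_age_years=int(elig_raw.get("max_age_years", 79)),
        min_enrollment_years=float(elig_raw.get("min_enrollment_years", 1)),
        min_encounters=int(elig_raw.get("min_encounters", 1)),
    )
    seeds = {k: int(v) for k, v in (raw.get("seeds") or {}).items()}
    sim_cfg = None
    if "simulate" in raw and raw["simulate"] is not None:
        from .records import Mechanism, ProblemType  # enum parsing

        sim_raw = raw["simulate"] if isinstance(raw["simulate"], dict) else {}
        kwargs: dict[str, Any] = {}
        if "n_patients" in sim_raw:
            kwargs["n_patients"] = int(sim_raw["n_patients"])
        kwargs["index_date"] = index_date
        if "age_range" in sim_raw:
            kwargs["age_range"] = tuple(sim_raw["age_range"])
        if "prevalence" in sim_raw:
            kwargs["prevalence"] = {
                Disease(k): float(v) for k, v in sim_raw["prevalence"].items()
            }
        if "mechanism_rates" in sim_raw:
            kwargs["mechanism_rates"] = {
                Disease(d): {Mechanism(m): float(r) for m, r in rates.items()}
                for d, rates in sim_raw["mechanism_rates"].items()
            }
        if "problem_type_mix" in sim_raw:
            kwargs["problem_type_mix"] = {
                Disease(d): {ProblemType(p): float(w) for p, w in mix.items()}
                for d, mix in sim_raw["problem_type_mix"].items()
            }
        for k in ("ineligible_fraction", "encounter_mean", "distractor_mean",
                  "corrected_error_rate"):
            if k in sim_raw:
                kwargs[k] = float(sim_raw[k])
        kwargs["seed"] = seeds.get("simulate", 11)
        sim_cfg = SimulationConfig(**kwargs)
    return RunConfig(
        index_date=index_date,
        eligibility=eligibility,
        ci_method=str(raw.get("ci_method", "wilson")),
        ci_level=float(raw.get("ci_level", 0.95)),
        per_stratum=int(raw.get("per_stratum", 300)),
        seeds=seeds or {"simulate": 11, "sample": 17},
        simulate=sim_cfg,
        paths={k: str(v) for k, v in (raw.get("paths") or {}).items()},
    )


# ---------------------------------------------------------------------------
# Calls CSV

CALLS_COLUMNS = ["patient_id", "disease", "positive", "triggering_codes"]


def write_calls(calls: list[PhenotypeCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CALLS_COLUMNS)
        for c in calls:
            trig = ";".join(f"{v}:{code}:{d.isoformat()}" for v, code, d in c.triggering_codes)
            writer.writerow([c.patient_id, c.disease.value, "true" if c.positive else "false", trig])


def read_calls(path: str | Path) -> list[PhenotypeCall]:
    calls = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            trig_list = []
            for part in row["triggering_codes"].split(";"):
                if not part:
                    continue
                rest, dstr = part.rsplit(":", 1)
                vocab, code = rest.split(":", 1)
                trig_list.append((vocab, code, date.fromisoformat(dstr)))
            trig = tuple(trig_list)
            calls.append(
                PhenotypeCall(
                    patient_id=row["patient_id"],
                    disease=Disease(row["disease"]),
                    positive=row["positive"] == "true",
                    triggering_codes=trig,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Report bundle


@dataclass
class ReportBundle:
    flow: dict
    strata: list[dict]
    operating: list[dict]
    taxonomy_mechanism: list[dict]
    taxonomy_problem_type: list[dict]
    provenance: dict

    def as_dict(self) -> dict:
        return {
            "flow": self.flow,
            "strata": self.strata,
            "operating_characteristics": self.operating,
            "taxonomy_mechanism": self.taxonomy_mechanism,
            "taxonomy_problem_type": self.taxonomy_problem_type,
            "provenance": self.provenance,
        }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> ReportBundle:
    """Execute every stage and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: inputs (generate or load) ---
    try:
        if config.simulate is not None:
            sim = generate_cohort(config.simulate)
            cohort, gold = sim.cohort, sim.gold
            concepts = sim.concept_sets
            catalog, _ = default_concept_sets()
            write_cohort(cohort, out / "cohort.jsonl")
            write_gold_labels(gold, out / "gold.csv")
            sim.manifest.to_csv(out / "manifest.csv", index=False)
            write_concept_set(concepts[Disease.CAVD], catalog, out / "concepts_cavd.csv")
            write_concept_set(concepts[Disease.CEVD], catalog, out / "concepts_cevd.csv")
        else:
            cohort = read_cohort(config.paths["cohort"])
            concepts = {
                Disease.CAVD: read_concept_set(config.paths["concepts_cavd"]),
                Disease.CEVD: read_concept_set(config.paths["concepts_cevd"]),
            }
            gold = (
                read_gold_labels(config.paths["gold"])
                if "gold" in config.paths
                else None
            )
    except Exception as exc:
        raise PipelineError(f"stage inputs: {exc}") from exc

    # --- stage: eligibility + flow ---
    try:
        eligible = [p for p in cohort if is_eligible(p, config.eligibility)]
        flow = flow_summary(len(cohort), len(cohort) - len(eligible))
        (out / "flow.txt").write_text(flow.render())
    except Exception as exc:
        raise PipelineError(f"stage eligibility: {exc}") from exc

    # --- stage: classification + grouping ---
    try:
        calls, groups = classify_cohort(
            eligible, concepts[Disease.CAVD], concepts[Disease.CEVD], config.index_date
        )
        write_calls(calls, out / "calls.csv")
        group_ids: dict[int, list[str]] = {g: [] for g in (1, 2, 3, 4)}
        for ga in groups:
            group_ids[ga.group].append(ga.patient_id)
    except Exception as exc:
        raise PipelineError(f"stage classify: {exc}") from exc

    # --- stage: stratified sampling ---
    try:
        sampled, _ = stratified_sample(
            group_ids, per_stratum=config.per_stratum, seed=config.seeds.get("sample", 17)
        )
        sampled_ids = {pid for ids in sampled.values() for pid in ids}
        with open(out / "sample.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["patient_id", "group", "sampled"])
            for ga in groups:
                writer.writerow(
                    [ga.patient_id, ga.group, "true" if ga.patient_id in sampled_ids else "false"]
                )
        strata = strata_table({g: len(ids) for g, ids in sampled.items()})
    except Exception as exc:
        raise PipelineError(f"stage sample: {exc}") from exc

    # --- stage: validation (skipped without gold labels) ---
    operating: list[dict] = []
    tax_mech: list[dict] = []
    tax_pt: list[dict] = []
    if gold is None:
        logger.warning("no gold labels configured; validation stage skipped")
    else:
        try:
            sample_calls = [c for c in calls if c.patient_id in sampled_ids]
            sample_gold = [g for g in gold if g.patient_id in sampled_ids]
            for scope in (Disease.CAVD, Disease.CEVD, "combined"):
                oc = operating_characteristics(
                    sample_calls, sample_gold, scope,
                    level=config.ci_level, ci_method=config.ci_method,
                )
                operating.append(oc.as_dict())
            _, mech_df, pt_df = error_taxonomy(sample_calls, sample_gold)
            tax_mech = mech_df.to_dict(orient="records")
            tax_pt = pt_df.to_dict(orient="records")
        except Exception as exc:
            raise PipelineError(f"stage validate: {exc}") from exc

    bundle = ReportBundle(
        flow=flow.as_dict(),
        strata=strata,
        operating=operating,
        taxonomy_mechanism=tax_mech,
        taxonomy_problem_type=tax_pt,
        provenance={
            "config_hash": config.hash(),
            "seeds": dict(sorted(config.seeds.items())),
            "version": __version__,
            "ci_method": config.ci_method,
            "combined_outcome": "test-positive if positive for either disease; "
            "gold-positive if true for either disease",
        },
    )
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.canonical(), fh, sort_keys=True)
    render_tables(bundle, "json", out)
    render_tables(bundle, "tsv", out)
    return bundle


def _df(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame.from_records(records)


def render_tables(bundle: ReportBundle, fmt: str, out_dir: str | Path) -> list[Path]:
    """Render the bundle's tables as tsv, markdown or a single json file.

    Every rendered number is taken verbatim from the bundle; percent cells
    are already fixed to 2 decimals upstream.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if fmt == "json":
        path = out / "report_bundle.json"
        path.write_text(json.dumps(bundle.as_dict(), sort_keys=True, indent=2) + "\n")
        return [path]
    if fmt not in {"tsv", "markdown"}:
        raise PipelineError(f"unknown report format {fmt!r}")

    def flat_operating() -> pd.DataFrame:
        rows = []
        for oc in bundle.operating:
            rows.append(
                {
                    "scope": oc["scope"],
                    **{k: oc["table"][k] for k in ("tp", "fp", "fn", "tn")},
                    "sensitivity": oc["sensitivity"]["value"],
                    "sens_ci_low": oc["sensitivity"]["ci_low"],
                    "sens_ci_high": oc["sensitivity"]["ci_high"],
                    "specificity": oc["specificity"]["value"],
                    "spec_ci_low": oc["specificity"]["ci_low"],
                    "spec_ci_high": oc["specificity"]["ci_high"],
                    "kappa": oc["kappa"]["value"],
                    "kappa_ci_low": oc["kappa"]["ci_low"],
                    "kappa_ci_high": oc["kappa"]["ci_high"],
                    "ci_method": oc["sensitivity"]["ci_method"],
                }
            )
        return pd.DataFrame.from_records(rows)

    tables = {
        "strata": _df(bundle.strata),
        "operating_characteristics": flat_operating(),
        "taxonomy_mechanism": _df(bundle.taxonomy_mechanism),
        "taxonomy_problem_type": _df(bundle.taxonomy_problem_type),
    }
    for name, df in tables.items():
        if fmt == "tsv":
            path = out / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
        else:
            path = out / f"{name}.md"
            path.write_text(df.to_markdown(index=False) + "\n" if not df.empty else "(empty)\n")
        written.append(path)
    return written
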