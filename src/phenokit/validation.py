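"""Operating characteristics against the chart-review gold standard.

Each algorithm call is scored against the per-patient, per-disease gold
label as TP/FP/TN/FN, for each disease separately and for the combined
outcome (positive-if-either on both axes).  From the 2x2 table we report
sensitivity, specificity and Cohen's kappa, each with a 95% CI, and
tabulate the discordant cases by mechanism and by clinical problem type.

Binomial CIs default to the Wilson score interval (Clopper-Pearson and the
normal approximation are available); reports always name the method.  The
kappa CI uses the large-sample variance of Fleiss, Cohen and Everitt.
Percentages are round-half-up to 2 decimals everywhere a table prints
"n (%)".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .concepts import Disease
from .records import (
    FN_MECHANISMS,
    FP_MECHANISMS,
    GoldLabel,
    Mechanism,
    ProblemType,
)
from .phenotyper import PhenotypeCall

CIMethod = Literal["wilson", "clopper_pearson", "normal"]

_STATSMODELS_METHOD = {
    "wilson": "wilson",
    "clopper_pearson": "beta",
    "normal": "normal",
}


class ValidationError(ValueError):
    pass


def percent(count: int, total: int) -> float:
    """100*count/total, round-half-up to 2 decimals (the "n (%)" convention)."""
    if total <= 0:
        raise ValidationError(f"percent: total must be positive, got {total}")
    if count < 0 or count > total:
        raise ValidationError(f"percent: count {count} outside [0, {total}]")
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    return float(q)


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its confidence interval."""

    value: float | None
    ci_low: float | None
    ci_high: float | None
    ci_level: float = 0.95
    ci_method: str = "wilson"
    defined: bool = True

    def as_dict(self) -> dict:
        return {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
            "defined": self.defined,
        }


@dataclass(frozen=True)
class TwoByTwo:
    """Confusion matrix of algorithm call (test) vs chart review (truth)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("TwoByTwo counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


def proportion_ci(
    k: int, n: int, level: float = 0.95, method: CIMethod = "wilson"
) -> tuple[float, float]:
    """Confidence interval for a binomial proportion, clipped to [0, 1]."""
    if not 0 <= k <= n or n <= 0:
        raise ValidationError(f"proportion_ci: need 0 <= k <= n, n > 0; got k={k}, n={n}")
    if not 0 < level < 1:
        raise ValidationError(f"proportion_ci: level must be in (0,1), got {level}")
    if method not in _STATSMODELS_METHOD:
        raise ValidationError(f"unknown CI method {method!r}")
    low, high = proportion_confint(k, n, alpha=1 - level, method=_STATSMODELS_METHOD[method])
    return (float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0)))


def _proportion_estimate(
    k: int, n: int, level: float, method: CIMethod
) -> Estimate:
    if n == 0:
        return Estimate(None, None, None, level, method, defined=False)
    low, high = proportion_ci(k, n, level, method)
    return Estimate(k / n, low, high, level, method)


def sensitivity(
    t: TwoByTwo, level: float = 0.95, method: CIMethod = "wilson"
) -> Estimate:
    """TP/(TP+FN); undefined (flagged) when there are no gold positives."""
    return _proportion_estimate(t.tp, t.tp + t.fn, level, method)


def specificity(
    t: TwoByTwo, level: float = 0.95, method: CIMethod = "wilson"
) -> Estimate:
    """TN/(TN+FP); undefined (flagged) when there are no gold negatives."""
    return _proportion_estimate(t.tn, t.tn + t.fp, level, method)


def cohen_kappa(table: Sequence[Sequence[float]], level: float = 0.95) -> Estimate:
    """Chance-corrected agreement kappa = (p_o - p_e)/(1 - p_e) with CI.

    ``table`` is a square agreement table (rows: rater/test one, columns:
    rater/test two).  The CI is the Wald interval based on the asymptotic
    variance of Fleiss, Cohen & Everitt (1969).  Degenerate marginals
    (p_e = 1) leave kappa undefined, flagged rather than raised.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError(f"cohen_kappa: table must be square, got {arr.shape}")
    if (arr < 0).any():
        raise ValidationError("cohen_kappa: counts must be non-negative")
    n = arr.sum()
    if n <= 0:
        raise ValidationError("cohen_kappa: empty table")
    p = arr / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        return Estimate(None, None, None, level, "asymptotic", defined=False)
    kappa = (p_o - p_e) / (1 - p_e)

    # Fleiss-Cohen-Everitt large-sample variance
    diag = np.diag(p)
    term1 = float(np.sum(diag * ((1 - p_e) - (row + col) * (1 - p_o)) ** 2))
    cross = (col[:, None] + row[None, :]) ** 2  # (p_.i + p_j.)^2 for cell (i, j)
    off = p * cross
    np.fill_diagonal(off, 0.0)
    term2 = (1 - p_o) ** 2 * float(off.sum())
    term3 = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = (term1 + term2 - term3) / (n * (1 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    z = sps.norm.ppf(0.5 + level / 2)
    return Estimate(
        value=float(kappa),
        ci_low=max(-1.0, float(kappa - z * se)),
        ci_high=min(1.0, float(kappa + z * se)),
        ci_level=level,
        ci_method="asymptotic",
    )


def interrater_agreement(
    labels_a: Sequence[GoldLabel],
    labels_b: Sequence[GoldLabel],
    level: float = 0.95,
) -> Estimate:
    """Cohen's kappa between two reviewers' labels on a shared record set."""
    key = lambda g: (g.patient_id, g.disease.value)
    a = {key(g): g.truth for g in labels_a}
    b = {key(g): g.truth for g in labels_b}
    if set(a) != set(b):
        only_a = sorted(set(a) - set(b))[:5]
        only_b = sorted(set(b) - set(a))[:5]
        raise ValidationError(
            f"reviewers labelled different records (a-only: {only_a}, b-only: {only_b})"
        )
    if not a:
        raise ValidationError("no shared records")
    table = np.zeros((2, 2))
    for k, ta in a.items():
        table[0 if ta else 1, 0 if b[k] else 1] += 1
    return cohen_kappa(table, level=level)


# ---------------------------------------------------------------------------
# Confusion matrices

DiseaseScope = Disease | Literal["combined"]


def _index_calls(calls: Iterable[PhenotypeCall]) -> dict[tuple[str, Disease], bool]:
    out: dict[tuple[str, Disease], bool] = {}
    for c in calls:
        k = (c.patient_id, c.disease)
        if k in out:
            raise ValidationError(f"duplicate call for {k}")
        out[k] = c.positive
    return out


def _index_gold(gold: Iterable[GoldLabel]) -> dict[tuple[str, Disease], GoldLabel]:
    out: dict[tuple[str, Disease], GoldLabel] = {}
    for g in gold:
        k = (g.patient_id, g.disease)
        if k in out:
            raise ValidationError(f"duplicate gold label for {k}")
        out[k] = g
    return out


def confusion_matrix(
    calls: Sequence[PhenotypeCall],
    gold: Sequence[GoldLabel],
    disease: DiseaseScope,
) -> TwoByTwo:
    """Score calls against gold labels for one disease or the combined outcome.

    For ``"combined"`` a patient counts as test-positive if positive for
    either disease and gold-positive if true for either; both per-disease
    calls and labels must then exist for every patient.
    """
    call_ix = _index_calls(calls)
    gold_ix = _index_gold(gold)
    tp = fp = fn = tn = 0
    if disease == "combined":
        patients = sorted({pid for pid, _ in call_ix})
        missing = [
            (pid, d.value)
            for pid in patients
            for d in Disease
            if (pid, d) not in gold_ix or (pid, d) not in call_ix
        ]
        if missing:
            raise ValidationError(
                f"combined outcome needs both diseases per patient; missing {missing[:10]}"
            )
        for pid in patients:
            test = call_ix[(pid, Disease.CAVD)] or call_ix[(pid, Disease.CEVD)]
            truth = gold_ix[(pid, Disease.CAVD)].truth or gold_ix[(pid, Disease.CEVD)].truth
            tp += test and truth
            fp += test and not truth
            fn += truth and not test
            tn += not test and not truth
    else:
        keys = sorted(k for k in call_ix if k[1] is disease)
        missing = [k for k in keys if k not in gold_ix]
        if missing:
            raise ValidationError(
                f"calls without gold labels: {[(p, d.value) for p, d in missing[:10]]}"
            )
        for k in keys:
            test, truth = call_ix[k], gold_ix[k].truth
            tp += test and truth
            fp += test and not truth
            fn += truth and not test
            tn += not test and not truth
    return TwoByTwo(tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn))


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Sensitivity / specificity / kappa row of the performance table."""

    scope: str
    table: TwoByTwo
    sensitivity: Estimate
    specificity: Estimate
    kappa: Estimate

    def as_dict(self) -> dict:
        return {
            "scope": self.scope,
            "table": self.table.as_dict(),
            "sensitivity": self.sensitivity.as_dict(),
            "specificity": self.specificity.as_dict(),
            "kappa": self.kappa.as_dict(),
        }


def operating_characteristics(
    calls: Sequence[PhenotypeCall],
    gold: Sequence[GoldLabel],
    disease: DiseaseScope,
    level: float = 0.95,
    ci_method: CIMethod = "wilson",
) -> OperatingCharacteristics:
    t = confusion_matrix(calls, gold, disease)
    agreement = [[t.tp, t.fn], [t.fp, t.tn]]  # rows: truth, cols: test
    return OperatingCharacteristics(
        scope=disease.value if isinstance(disease, Disease) else str(disease),
        table=t,
        sensitivity=sensitivity(t, level, ci_method),
        specificity=specificity(t, level, ci_method),
        kappa=cohen_kappa(agreement, level=level),
    )


# ---------------------------------------------------------------------------
# Error taxonomy (discordant cases by mechanism and by clinical problem)

UNANNOTATED = "unannotated"

# canonical presentation order: FN mechanisms, then FP mechanisms
_MECHANISM_ORDER = [
    Mechanism.CODE_NOT_IN_SET,
    Mechanism.FREETEXT_ONLY,
    Mechanism.CODE_NOT_DETECTED,
    Mechanism.ERRONEOUS_DATE,
    Mechanism.DISMISSED_DIAGNOSIS,
    Mechanism.INCIDENTAL_NO_RELEVANCE,
    Mechanism.CODE_WITHOUT_NOTE,
    Mechanism.INCORRECT_ABBREVIATION,
]
_PROBLEM_ORDER = [
    ProblemType.PVD,
    ProblemType.CHF,
    ProblemType.MI,
    ProblemType.CAVD_SYMPTOM,
    ProblemType.STROKE,
    ProblemType.TIA,
]


@dataclass(frozen=True)
class ErrorCase:
    """One discordant (patient, disease) pair: a FP or FN of the algorithm."""

    patient_id: str
    disease: Disease
    kind: Literal["FP", "FN"]
    mechanism: Mechanism = Mechanism.NONE
    problem_type: ProblemType = ProblemType.NONE


def extract_error_cases(
    calls: Sequence[PhenotypeCall], gold: Sequence[GoldLabel]
) -> list[ErrorCase]:
    """Turn every call/gold discordance into an :class:`ErrorCase`.

    A discordant pair whose gold label carries no mechanism annotation is
    kept (it will surface as ``unannotated`` in the tables), never dropped.
    """
    call_ix = _index_calls(calls)
    gold_ix = _index_gold(gold)
    missing = sorted(k for k in call_ix if k not in gold_ix)
    if missing:
        raise ValidationError(
            f"calls without gold labels: {[(p, d.value) for p, d in missing[:10]]}"
        )
    cases: list[ErrorCase] = []
    for (pid, disease), test in sorted(call_ix.items(), key=lambda kv: (kv[0][0], kv[0][1].value)):
        g = gold_ix[(pid, disease)]
        if test == g.truth:
            continue
        cases.append(
            ErrorCase(
                patient_id=pid,
                disease=disease,
                kind="FP" if test else "FN",
                mechanism=g.mechanism,
                problem_type=g.problem_type,
            )
        )
    return cases


def _mech_label(m: Mechanism) -> str:
    return UNANNOTATED if m is Mechanism.NONE else m.value


def mechanism_table(cases: Sequence[ErrorCase]) -> pd.DataFrame:
    """Discordant cases tabulated by kind and mechanism.

    Columns mirror the published layout: share of all errors, share of the
    kind's (FP or FN) total, and share of each disease's kind total.  Every
    percentage is :func:`percent` of the printed count over the printed
    total, so rows and columns reconcile exactly.
    """
    total = len(cases)
    kind_totals = {k: sum(1 for c in cases if c.kind == k) for k in ("FN", "FP")}
    dk_totals = {
        (d, k): sum(1 for c in cases if c.disease is d and c.kind == k)
        for d in Disease
        for k in ("FN", "FP")
    }
    rows = []
    for kind in ("FN", "FP"):
        labels = [_mech_label(m) for m in _MECHANISM_ORDER] + [UNANNOTATED]
        seen: list[str] = []
        for label in labels:
            if label in seen:
                continue
            seen.append(label)
            sub = [c for c in cases if c.kind == kind and _mech_label(c.mechanism) == label]
            if not sub:
                continue
            count = len(sub)
            row = {
                "kind": kind,
                "category": label,
                "count": count,
                "pct_total_errors": percent(count, total),
                "pct_kind": percent(count, kind_totals[kind]),
            }
            for d in Disease:
                d_count = sum(1 for c in sub if c.disease is d)
                denom = dk_totals[(d, kind)]
                row[f"{d.value}_count"] = d_count
                row[f"pct_{d.value}_{kind}"] = percent(d_count, denom) if denom else None
            rows.append(row)
    cols = [
        "kind", "category", "count", "pct_total_errors", "pct_kind",
        "CaVD_count", "pct_CaVD_FN", "pct_CaVD_FP",
        "CeVD_count", "pct_CeVD_FN", "pct_CeVD_FP",
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=[c for c in cols if "pct_Ca" not in c and "pct_Ce" not in c])
    # per-row only the matching kind's disease share is meaningful; merge into two columns
    df["pct_CaVD_kind"] = df.apply(lambda r: r[f"pct_CaVD_{r['kind']}"], axis=1)
    df["pct_CeVD_kind"] = df.apply(lambda r: r[f"pct_CeVD_{r['kind']}"], axis=1)
    return df[
        ["kind", "category", "count", "pct_total_errors", "pct_kind",
         "CaVD_count", "pct_CaVD_kind", "CeVD_count", "pct_CeVD_kind"]
    ]


def problem_type_table(cases: Sequence[ErrorCase]) -> pd.DataFrame:
    """Discordant cases tabulated by clinical problem type.

    Shares are of all errors, of the FN total, of the FP total, and of each
    disease's error total; all denominators are the table's own counts.
    """
    total = len(cases)
    fn_total = sum(1 for c in cases if c.kind == "FN")
    fp_total = sum(1 for c in cases if c.kind == "FP")
    disease_totals = {d: sum(1 for c in cases if c.disease is d) for d in Disease}
    rows = []
    labels = [p for p in _PROBLEM_ORDER] + [ProblemType.NONE]
    for pt in labels:
        sub = [c for c in cases if c.problem_type is pt]
        if not sub:
            continue
        count = len(sub)
        fn = sum(1 for c in sub if c.kind == "FN")
        fp = count - fn
        row = {
            "problem_type": UNANNOTATED if pt is ProblemType.NONE else pt.value,
            "count": count,
            "pct_total_errors": percent(count, total),
            "fn_count": fn,
            "pct_fn": percent(fn, fn_total) if fn_total else None,
            "fp_count": fp,
            "pct_fp": percent(fp, fp_total) if fp_total else None,
        }
        for d in Disease:
            d_count = sum(1 for c in sub if c.disease is d)
            denom = disease_totals[d]
            row[f"{d.value}_count"] = d_count
            row[f"pct_{d.value}_errors"] = percent(d_count, denom) if denom else None
        rows.append(row)
    cols = [
        "problem_type", "count", "pct_total_errors", "fn_count", "pct_fn",
        "fp_count", "pct_fp", "CaVD_count", "pct_CaVD_errors",
        "CeVD_count", "pct_CeVD_errors",
    ]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def error_taxonomy(
    calls: Sequence[PhenotypeCall], gold: Sequence[GoldLabel]
) -> tuple[list[ErrorCase], pd.DataFrame, pd.DataFrame]:
    """Full qualitative-error analysis: cases + both taxonomy tables."""
    cases = extract_error_cases(calls, gold)
    return cases, mechanism_table(cases), problem_type_table(cases)


def check_mechanism_consistency(cases: Sequence[ErrorCase]) -> list[str]:
    """Flag cases whose annotated mechanism contradicts their FP/FN kind."""
    problems = []
    for c in cases:
        if c.kind == "FP" and c.mechanism in FN_MECHANISMS:
            problems.append(f"{c.patient_id}/{c.disease.value}: FP with FN mechanism {c.mechanism.value}")
        if c.kind == "FN" and c.mechanism in FP_MECHANISMS:
            problems.append(f"{c.patient_id}/{c.disease.value}: FN with FP mechanism {c.mechanism.value}")
    return problems
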