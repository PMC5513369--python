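# Methods

## The detection rule

A patient is called positive for a disease at an index date `t0` when the
problem list contains at least one entry whose `(vocabulary, code)` belongs
to the disease's concept set, whose status is `active` or `passive`, and
whose recorded date is strictly before `t0`. Entries statused `error`
never contribute, and — because status is carried per entry — an
error-statused duplicate never vetoes a distinct qualifying entry. The
observation window is unbounded on the left: codes predating EMR
implementation are treated as past medical history. There is no free-text
component; a chart-positive patient without qualifying codes is simply
missed (that failure mode is itself part of the error taxonomy).

Eligibility at `t0`: completed (birthday-based) age within `[40, 79]`,
enrollment starting at least one year before `t0` with enrollment still
active at `t0` (enrollment is modelled as a single interval — coverage gaps
are out of scope), and at least one encounter before `t0`. Each failed
check is reported by name.

Groups: the two per-disease calls map to 1 = neither, 2 = CaVD only,
3 = CeVD only, 4 = both. The stratified validation sample draws up to
`per_stratum` (default 300) patients per group uniformly without
replacement; a smaller group is taken whole with a warning, which is the
normal situation for the both-diseases stratum.

## Validation statistics

* Binomial proportions (sensitivity, specificity) carry a Wilson score
  interval by default; Clopper–Pearson (`beta`) and the normal
  approximation are selectable, and every report names the method used.
  Intervals are clipped to `[0, 1]`. The interval computation is delegated
  to `statsmodels.stats.proportion.proportion_confint`.
* Cohen's κ = (p_o − p_e)/(1 − p_e) is implemented in-package with the
  Fleiss–Cohen–Everitt (1969) large-sample variance for its Wald CI;
  degenerate marginals (p_e = 1) yield a flagged undefined result rather
  than an exception. The implementation is cross-checked in the tests
  against `statsmodels.stats.inter_rater.cohens_kappa` to 1e-9.
* The combined outcome is positive-if-either on both axes: a patient is
  test-positive if either disease call fires and gold-positive if either
  chart label is true. Report headers state this definition.
* All "n (%)" cells use round-half-up to two decimals
  (`percent(count, total)`); taxonomy tables derive every percentage from
  their own printed counts, so rows, columns and margins reconcile
  exactly. Discordant cases lacking a mechanism annotation surface as an
  explicit `unannotated` category, never silently dropped.

## The synthetic cohort generator

The generator emulates a problem-list EMR audited against charts. Each
(patient, disease) pair is drawn from a categorical distribution over
{concordant positive, concordant negative, one of seven discordance
mechanisms}. Mechanism probabilities are absolute per-pair rates:
false-negative mechanisms (out-of-set code, free-text-only event,
erroneous date) are carved out of the prevalence mass, false-positive
mechanisms (dismissed diagnosis, incidental finding, code without note,
incorrect abbreviation) out of its complement. Feasibility therefore
requires FN mass ≤ prevalence and FP mass ≤ 1 − prevalence, checked on
construction. Because pair categories map deterministically to codes —
and the planting pools for the two diseases are kept disjoint, with
distractor codes drawn only from terms outside both concept sets — the
manifest's expected call is exact, mechanism recall by the taxonomy is
perfect by construction, and expected operating characteristics have
closed forms (per disease directly; for the combined outcome by exact
enumeration of the independent joint categories).

Defaults, chosen once as a realistic 40–79 HMO scenario:

| parameter | default | rationale |
|---|---|---|
| `n_patients` | 1200 | demo-scale cohort; validation designs of ~1100 are typical |
| `prevalence` | CaVD 0.12, CeVD 0.08 | plausible lifetime prevalence at ages 40–79 |
| `mechanism_rates` | ~2–3% total per disease | echo the published audit composition: dismissed diagnoses dominate CaVD FPs, incidental findings dominate CeVD FPs, out-of-set codes dominate FNs |
| `ineligible_fraction` | 0.027 | matches the few-percent exclusion rate seen in practice |
| `encounter_mean` | 6 | Poisson(5)+1 prior encounters per eligible patient |
| `distractor_mean` | 2 | Poisson count of non-cardiovascular codes per patient |
| `corrected_error_rate` | 0.05 | fraction of concordant negatives carrying a correctly error-statused in-set code, to exercise the status rule |
| ages | uniform over 40–79 at index | no published demographic structure to copy |
| enrollment start | uniform 400–3650 days pre-index | guarantees seniority for eligible patients |

What the generator does **not** emulate: free-text notes (free-text-only
events exist only as gold labels), correlated comorbidity between the two
diseases (pair categories are independent), longitudinal disease course,
coding-habit drift over time, and reviewer disagreement in the gold
standard (labels are exact). Passing recovery tests therefore demonstrate
that the pipeline measures what the generator planted — they do not
estimate how the rule would perform on real charts, which is exactly why
the published operating characteristics are not treated as reproducible
targets.

Randomness: each patient uses `numpy.random.default_rng([seed, i])`, so
cohorts are reproducible, growing `n_patients` leaves earlier patients
unchanged, and all seeds fit in 31 bits.

## Numerical and design choices

* **CI method default.** The source validation study does not state its
  CI method; Wilson is the default for its coverage at moderate n, and the
  method is recorded in every output.
* **Rounding.** Published tables of this kind mix rounding conventions
  (some cells are truncations, some one-decimal roundings). This package
  commits to round-half-up at two decimals everywhere; table cells that
  can only be obtained by truncation are not asserted in tests, and
  one-decimal cells are compared at their printed precision.
* **Per-disease taxonomy denominators.** Published per-disease share
  columns in problem-type tables are sometimes internally inconsistent
  with their own stated totals (e.g. a share implying n = 60 against a
  stated n = 62). `problem_type_table` always derives per-disease shares
  from its own counts; the inconsistent published cells are excluded from
  any comparison.
* **`code_not_detected`.** Kept as a distinct taxonomy label, but folded
  into `code_not_in_set` for generation — no generative detail
  distinguishes a code the query missed from a code outside the set.
* **Mechanism rates per disease.** Rates are a mapping
  disease → mechanism → probability (rather than one flat mapping),
  because the observed error composition differs sharply between the two
  diseases.
* **Determinism.** Sampling sorts candidate ids before drawing; report
  bundles are JSON with sorted keys and contain no timestamps, so
  identical configs re-run byte-identically.
* **Problem sizes.** The recovery analyses use 2000-patient cohorts
  (≈3900 eligible pairs per disease), which puts 3 Monte-Carlo SE at
  roughly 2–7 percentage points on the recovered proportions; the
  replicate-mean oracle uses 200 cohorts of 150 patients. These sizes make
  the checks sharp while keeping the whole suite fast.

## Known limitations

* Keyword selection over descriptions is a stand-in for a real
  terminology-server query; no hierarchical (descendants-of) expansion.
* The bundled catalog (~66 terms) is synthetic; real concept sets are
  orders of magnitude larger and vocabulary mapping is genuinely hard.
* Verification bias is not modelled: operating characteristics computed on
  a test-result-stratified sample are conditioned on that design, as in
  the source study.
* Single enrollment interval per patient; no coverage gaps.
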