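# phenokit

Rule-based electronic phenotyping of cardiovascular (CaVD) and
cerebrovascular (CeVD) disease from coded EMR problem lists, with the full
validation machinery around it.

## The problem

Observational studies built on electronic medical records need to know
whether a patient has actually had an event — an infarction, a stroke,
heart failure — using only what the record contains. In a problem-oriented
EMR the cheapest detector is a *codes-based rule*: assemble a concept set
(a list of coded signs, symptoms, diagnoses and procedures for the disease)
and call a patient positive if at least one of those codes appears in the
problem list before an index date, provided the entry was never statused as
an `error`. Such a rule is simple and fast, but problem lists diverge from
chart truth in systematic ways — dismissed diagnoses left active,
incidental findings coded as disease, events living only in free text — so
the rule must be *validated* against manual chart review, and its failures
understood.

`phenokit` implements that whole loop for two phenotypes assessed at an
index date (default 2005-01-01) in an HMO-style population aged 40–79 with
at least one year of enrollment and one prior encounter:

* **concept sets** — keyword selection over a terminology catalog
  (SNOMED-CT-like, ICD-10-like, ICPC-2-like and local codes), merged across
  reviewers by sensitivity-maximizing union, persisted as CSV;
* **detection rule** — positive iff an included `(vocabulary, code)` with
  status `active`/`passive` is recorded strictly before the index date;
* **four groups and stratified sampling** — patients fall into
  negative / CaVD-only / CeVD-only / both, and a validation sample is
  drawn with (approximately) equal strata to enrich for positives;
* **operating characteristics** — sensitivity TP/(TP+FN), specificity
  TN/(TN+FP) and Cohen's κ = (p_o − p_e)/(1 − p_e) against gold labels,
  each with 95% CIs (Wilson by default; Clopper–Pearson and normal
  available), per disease and for the combined positive-if-either outcome;
* **error taxonomy** — every FP/FN tabulated by mechanism (dismissed
  diagnosis, incidental finding, code without note, wrong abbreviation,
  out-of-set code, free-text-only event, erroneous date) and by clinical
  problem (PVD, CHF, MI, cardiovascular symptoms, stroke, TIA);
* **synthetic cohorts** — a generator that plants those mechanisms at
  configurable per-pair rates with known gold labels, so the pipeline's
  statistical behaviour can be verified by parameter recovery against
  closed-form expectations.

No real patient data is included or required; the bundled terminology
catalog is a synthetic stand-in.

## Worked example

Run the bundled demo — simulate 1200 patients, classify, sample, validate:

```
$ phenokit run --out-dir out/
flow: {'drawn': 1200, 'ineligible': 24, 'included': 1176}
stratum 1 (both absent): 60 (31.58%)
stratum 2 (CaVD only): 60 (31.58%)
stratum 3 (CeVD only): 60 (31.58%)
stratum 4 (both present): 10 (5.26%)
CaVD: sens 0.887, spec 0.883, kappa 0.745
CeVD: sens 1.000, spec 0.839, kappa 0.721
combined: sens 0.970, spec 0.633, kappa 0.614
report bundle written under out/
```

Reading the output: of 1200 simulated patients, 24 fail the inclusion
criteria (age 40–79 at index, one year of enrollment seniority, at least
one prior encounter) and 1176 enter the analysis. The stratified review
sample takes up to 60 patients per algorithm-defined group; the
both-diseases stratum holds only 10 patients, so it is taken whole — the
same unequal-strata situation that arises in real validation studies. The
bottom rows score the algorithm against the simulated chart truth on that
sample: per-disease sensitivity and specificity are high, while the
combined rule (used to *exclude* anyone with either disease) trades
specificity for sensitivity — exactly the behaviour this kind of
union-of-codes rule shows on real records, because planted false-positive
mechanisms accumulate across diseases. All numbers, with their confidence
intervals and the FP/FN taxonomy tables, are in `out/report_bundle.json`
and the accompanying TSVs; re-running with the same config reproduces
every file byte-for-byte.

The library surface mirrors the pipeline: `select_terms` /
`merge_reviewer_selections`, `classify_patient`, `assign_group`,
`stratified_sample`, `confusion_matrix`, `sensitivity` / `specificity` /
`cohen_kappa`, `error_taxonomy`, and `generate_cohort` /
`expected_operating_characteristics`.

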