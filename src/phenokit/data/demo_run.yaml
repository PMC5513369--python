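# Demo run: simulate a cohort with the bundled concept sets, classify it,
# draw the stratified review sample and validate against the simulated gold
# standard.  All stages are deterministic given the seeds below.
index_date: 2005-01-01
eligibility:
  min_age_years: 40
  max_age_years: 79
  min_enrollment_years: 1
  min_encounters: 1
ci_method: wilson
ci_level: 0.95
per_stratum: 60
seeds:
  simulate: 11
  sample: 17
simulate:
  n_patients: 1200
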