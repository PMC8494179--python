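# Default parameterization of the thyroid-cancer ultrasound-screening
# decision model: six health states, two strategies (SG = annual ultrasound
# screening, NSG = routine physical examination), annual cycles.
# Gamma shape_b is a scale (mean = shape_a * shape_b); Beta shapes are used
# as printed, except that a degenerate Beta is repaired by moment matching.
schema_version: 1
settings:
  horizon_cycles: 55
  cycle_length: 1.0
  start_age: 20
  discount_rate: 0.05
  wtp_threshold: 50000.0
  psa_draws: 1000
  rng_seed: 0
# Calibrated structural switches reproducing the published base case:
# rewards credited at cycle end; annual ultrasound reaches every living
# member of the screening arm while the comparator's routine physical is
# charged only before a nodule/cancer enters dedicated follow-up; the
# 55-year horizon equals the cohort's remaining life expectancy, so no
# background deaths occur within it (swap in kind: synthetic for a
# Gompertz-Makeham life table, or kind: csv with path: to supply one).
calibration:
  discount_timing: end
  half_cycle_correction: false
  screening_per_cycle: true
  exam_states_sg: [health, benign, malignant, postop, recurrence]
  exam_states_nsg: [health]
life_table:
  kind: none
parameters:
  utility.recurrence:
    {base: 0.54, low: 0.49, high: 0.59, family: beta, shape_a: 176, shape_b: 150}
  utility.postop:
    {base: 0.99, low: 0.74, high: 1.00, family: beta, shape_a: 1, shape_b: 0}
  utility.malignant:
    {base: 0.60, low: 0.54, high: 0.66, family: beta, shape_a: 153, shape_b: 102}
  utility.benign:
    {base: 0.99, low: 0.89, high: 1.00, family: beta, shape_a: 100, shape_b: 1}
  utility.health:
    {base: 1.0, family: fixed}
  utility.death:
    {base: 0.0, family: fixed}
  cost.treatment:
    {base: 20174.5786, low: 16737.47, high: 24283.81, family: gamma, shape_a: 29, shape_b: 706}
  cost.screening_exam:
    {base: 251.46, low: 126.06, high: 311.52, family: gamma, shape_a: 7, shape_b: 34}
  cost.cancer_followup:
    {base: 1264.9032, low: 731.99, high: 2309.31, family: gamma, shape_a: 3, shape_b: 492}
  cost.nodule_followup:
    {base: 798.6, low: 399.30, high: 1597.20, family: gamma, shape_a: 2, shape_b: 449}
  cost.recurrence:
    # published upper bound is garbled; repaired as 1.5x the base value
    {base: 6050.22, low: 3024.78, high: 9075.33, family: gamma, shape_a: 4, shape_b: 1513}
  cost.physical_exam:
    {base: 50.16, low: 25.08, high: 75.24, family: gamma, shape_a: 4, shape_b: 13}
  prob.health_to_benign.sg:
    {base: 0.19, low: 0.14, high: 0.24, family: beta, shape_a: 50, shape_b: 211}
  prob.health_to_benign.nsg:
    {base: 0.68, low: 0.51, high: 0.85, family: beta, shape_a: 19, shape_b: 9}
  prob.health_to_malignant.sg:
    {base: 0.000039, low: 0.000029, high: 0.000049, family: beta, shape_a: 62, shape_b: 1575948}
  prob.health_to_malignant.nsg:
    {base: 0.000583, low: 0.000437, high: 0.000729, family: beta, shape_a: 61, shape_b: 105337}
  prob.benign_to_malignant:
    {base: 0.00854478, low: 0.00640859, high: 0.01068098, family: beta, shape_a: 61, shape_b: 7070}
  prob.malignant_to_death.sg:
    {base: 0.000003, low: 0.00000195, high: 0.00000325, family: beta, shape_a: 62, shape_b: 23640522}
  prob.malignant_to_death.nsg:
    {base: 0.000005, low: 0.000004, high: 0.000007, family: beta, shape_a: 62, shape_b: 11175470}
  prob.postop_to_recurrence:
    {base: 0.001029, low: 0.000772, high: 0.001286, family: beta, shape_a: 61, shape_b: 59621}
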