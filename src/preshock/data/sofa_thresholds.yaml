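# Sequential Organ Failure Assessment (SOFA) organ-dysfunction thresholds.
# Each organ system scores 0-4; the total is the sum over the six systems.
# version: 1 (Vincent et al. consensus table, as commonly operationalized from EHR data)
#
# Conventions used by the scorer:
#   - "lt" systems score i (1..4) when the worst (minimum) in-window value is
#     strictly below thresholds[i-1].
#   - "ge" systems score i when the worst (maximum) in-window value is at or
#     above thresholds[i-1].
#   - Respiration uses the PaO2/FiO2 ratio (mmHg); ventilation status is not
#     gated separately (ventilator charting is not part of the data model).
respiration:
  input: pao2_fio2_ratio
  direction: lt
  thresholds: [400.0, 300.0, 200.0, 100.0]
coagulation:
  input: platelets          # x10^3 / uL
  direction: lt
  thresholds: [150.0, 100.0, 50.0, 20.0]
liver:
  input: bilirubin          # mg/dL
  direction: ge
  thresholds: [1.2, 2.0, 6.0, 12.0]
cns:
  input: gcs                # Glasgow Coma Scale 3-15
  direction: lt
  thresholds: [15.0, 13.0, 10.0, 6.0]
renal:
  input: creatinine         # mg/dL (urine-output branch not used)
  direction: ge
  thresholds: [1.2, 2.0, 3.5, 5.0]
cardiovascular:
  map_threshold: 70.0       # MAP < 70 mmHg with no vasopressor -> score 1
  # Per-agent dose breakpoints (ug/kg/min except vasopressin, U/min).
  # score is 2 while dose <= score2_max, 3 while dose <= score3_max, else 4.
  # A missing score2_max means the agent enters at score 3.
  agents:
    norepinephrine: {score3_max: 0.1}
    epinephrine: {score3_max: 0.1}
    dopamine: {score2_max: 5.0, score3_max: 15.0}
    dobutamine: {score2_max: .inf}
    phenylephrine: {score3_max: 1.0}
    vasopressin: {score3_max: 0.04}
  default_agent: norepinephrine
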