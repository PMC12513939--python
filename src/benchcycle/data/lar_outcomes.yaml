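# Default outcome declarations for a LAR cohort.
outcomes:
  - {name: anastomotic_leak, kind: binary, direction: lower_better, units: "%"}
  - {name: readmission_3mo, kind: binary, direction: lower_better, units: "%"}
  - {name: cdc_ge_3a_discharge, kind: binary, direction: lower_better, units: "%"}
  - {name: ln_ge_12, kind: binary, direction: higher_better, units: "%"}
  - {name: los_days, kind: continuous, direction: lower_better, units: "days"}
  - {name: surgery_duration_min, kind: continuous, direction: lower_better, units: "min"}
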