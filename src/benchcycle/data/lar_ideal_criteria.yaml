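# Ideal-patient definition for elective low anterior resection (LAR).
# A patient is "ideal" iff every criterion below holds; any missing value
# on a criterion field classifies the patient as non-ideal.
name: lar_ideal
criteria:
  - {name: adult, field: age, op: ge, value: 18}
  - {name: age_below_80, field: age, op: lt, value: 80}
  - {name: bmi_at_least_20, field: bmi, op: ge, value: 20}
  - {name: bmi_below_35, field: bmi, op: lt, value: 35}
  - {name: albumin_at_least_3, field: albumin, op: ge, value: 3.0}
  - {name: asa_below_3, field: asa, op: lt, value: 3}
  - {name: no_recent_smoking, field: smoker, op: eq, value: false}
  - {name: no_anticoagulation, field: anticoagulation, op: eq, value: false}
  - {name: no_bleeding_disorder, field: bleeding_disorder, op: eq, value: false}
  - {name: no_copd, field: copd, op: eq, value: false}
  - {name: no_insulin_dependent_diabetes, field: insulin_dependent_diabetes, op: eq, value: false}
  - {name: no_immunosuppression_or_steroids, field: immunosuppression_or_steroids, op: eq, value: false}
  - {name: no_ibd, field: ibd, op: eq, value: false}
  - {name: no_prior_major_abdominal_surgery, field: prior_major_abdominal_surgery, op: eq, value: false}
  - {name: pt_stage_at_most_3, field: pT_stage, op: in, value: ["0", "is", "1", "2", "3"]}
  - {name: no_preop_chemotherapy, field: preop_chemotherapy, op: eq, value: false}
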