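# Published benchmark cut-offs for elective low anterior resection (LAR).
# cutoff = 75th percentile of reference-centre medians for lower-better
# outcomes (25th for higher-better); range = span of centre medians.
# Rates are in percentage points; continuous outcomes in native units.
name: lar_2022
entries:
  - procedure: LAR
    outcome: anastomotic_leak
    stratum: ideal
    cutoff: 9.8
    range_low: 0.0
    range_high: 15.6
    direction: lower_better
    units: "%"
    source: "LAR benchmark consortium, 2022 (19 reference centres)"
  - procedure: LAR
    outcome: ln_ge_12
    stratum: ideal
    cutoff: 74.5
    range_low: 65.5
    range_high: 100.0
    direction: higher_better
    units: "%"
    source: "LAR benchmark consortium, 2022 (19 reference centres)"
  - procedure: LAR
    outcome: ln_ge_12
    stratum: non_ideal
    cutoff: 68.3
    range_low: 54.3
    range_high: 94.7
    direction: higher_better
    units: "%"
    source: "LAR benchmark consortium, 2022 (19 reference centres)"
  - procedure: LAR
    outcome: cdc_ge_3a_discharge
    stratum: ideal
    cutoff: 12.2
    range_low: 2.3
    range_high: 16.7
    direction: lower_better
    units: "%"
    source: "LAR benchmark consortium, 2022 (19 reference centres)"
  - procedure: LAR
    outcome: cdc_ge_3a_discharge
    stratum: non_ideal
    cutoff: 13.7
    range_low: 3.3
    range_high: 26.0
    direction: lower_better
    units: "%"
    source: "LAR benchmark consortium, 2022 (19 reference centres)"
  - procedure: LAR
    outcome: readmission_3mo
    stratum: ideal
    cutoff: 15.3
    range_low: 0.0
    range_high: 19.0
    direction: lower_better
    units: "%"
    source: "LAR benchmark consortium, 2022 (19 reference centres)"
  - procedure: LAR
    outcome: readmission_3mo
    stratum: non_ideal
    cutoff: 21.7
    range_low: 3.2
    range_high: 28.6
    direction: lower_better
    units: "%"
    source: "LAR benchmark consortium, 2022 (19 reference centres)"
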