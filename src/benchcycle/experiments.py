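"""Seeded simulation experiments characterising run-rule behaviour.

Two standard studies, each replicated over many seeds on synthetic
cohorts:

* **Detection**: the 3-month readmission rate steps from 15% to 35% at
  the study midpoint in a centre operating ~20 patients/month.  We measure
  how often the k=2 consecutive-run rule fires a signal overlapping the
  post-change windows — the power of the monitoring scheme against a
  clinically gross deterioration.
* **Null calibration**: a centre performing comfortably within benchmark
  (every nominal rate at about half its cut-off distance; see
  :func:`null_scenario`), with enough volume that even the ideal stratum
  averages >= 40 patients per 18-month window.  We measure how often at
  least one spurious signal fires anywhere — the false-alarm rate of a
  whole surveillance cycle.
"""

from __future__ import annotations

from dataclasses import replace
from datetime import date

from .cohort import Stratum, packaged_outcomes
from .model import BenchmarkCycle
from .synthetic import CohortScenario, generate_cohort

STUDY_START = date(2018, 1, 1)
STUDY_END = date(2024, 1, 1)
MIDPOINT = date(2021, 1, 1)

#: Pre- and post-change readmission rates for the detection study.
DETECTION_BASE_RATE = 0.15
DETECTION_SHIFTED_RATE = 0.35
DETECTION_MONTHLY_VOLUME = 20.0

#: Null-study volume: 14/month x 18 months x 16.3% ideal ~= 41 ideal
#: patients per window.
NULL_MONTHLY_VOLUME = 14.0


def detection_scenario(seed: int) -> CohortScenario:
    """Readmission step change 0.15 -> 0.35 at the study midpoint."""
    return CohortScenario(
        study_start=STUDY_START,
        study_end=STUDY_END,
        monthly_volume=DETECTION_MONTHLY_VOLUME,
        binary_rates={
            "readmission_3mo": {
                "ideal": DETECTION_BASE_RATE,
                "non_ideal": DETECTION_BASE_RATE,
            }
        },
        continuous_params={},
        seed=seed,
    ).with_shift("readmission_3mo", MIDPOINT, DETECTION_SHIFTED_RATE)


def null_scenario(seed: int) -> CohortScenario:
    """All nominal rates strictly (and comfortably) better than cut-offs.

    Lower-is-better rates sit at roughly half their cut-off; the
    higher-is-better lymph-node yield sits midway between its cut-off and
    100%.  This represents a compliant centre whose residual deviations
    are pure sampling noise.
    """
    return CohortScenario(
        study_start=STUDY_START,
        study_end=STUDY_END,
        monthly_volume=NULL_MONTHLY_VOLUME,
        binary_rates={
            "anastomotic_leak": {"ideal": 0.05, "non_ideal": 0.05},
            "readmission_3mo": {"ideal": 0.075, "non_ideal": 0.11},
            "cdc_ge_3a_discharge": {"ideal": 0.06, "non_ideal": 0.07},
            "ln_ge_12": {"ideal": 0.873, "non_ideal": 0.84},
        },
        continuous_params={},
        seed=seed,
    )


def _fit(scenario: CohortScenario, k: int = 2):
    cohort = generate_cohort(scenario)
    outcomes = [s for s in packaged_outcomes() if s.name in scenario.binary_rates]
    model = BenchmarkCycle(
        cohort.records,
        outcomes=outcomes,
        study_start=scenario.study_start,
        study_end=scenario.study_end,
        k=k,
    )
    return model.fit()


def signal_overlaps_date(signal, windows, cut: date) -> bool:
    """True iff any window within the signal's run ends after ``cut``."""
    by_label = {w.label: w for w in windows}
    start = int(signal.start_label[1:])
    end = int(signal.end_label[1:])
    return any(
        by_label[f"p{i}"].end > cut for i in range(start, end + 1) if f"p{i}" in by_label
    )


def detection_rate(n_seeds: int = 200, base_seed: int = 0, k: int = 2) -> float:
    """Fraction of seeds where a signal overlaps the post-change windows."""
    hits = 0
    for i in range(n_seeds):
        res = _fit(detection_scenario(base_seed + i), k=k)
        found = any(
            signal_overlaps_date(sig, res.windows, MIDPOINT)
            for sigs in res.signals.values()
            for sig in sigs
        )
        hits += found
    return hits / n_seeds


def false_signal_rate(n_seeds: int = 200, base_seed: int = 0, k: int = 2) -> float:
    """Fraction of null-scenario seeds with >= 1 spurious signal anywhere."""
    hits = 0
    for i in range(n_seeds):
        res = _fit(null_scenario(base_seed + i), k=k)
        hits += res.any_signal
    return hits / n_seeds
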