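from datetime import date

import pytest

import benchcycle as bc


@pytest.fixture(scope="session")
def criteria():
    return bc.packaged_criteria("lar_ideal")


@pytest.fixture(scope="session")
def registry():
    return bc.load_registry("lar_2022")


@pytest.fixture(scope="session")
def outcome_specs():
    return bc.packaged_outcomes()


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic study-like cohort: 72 months, ~1.4 ops/month, seed fixed."""
    return bc.generate_cohort(bc.CohortScenario(seed=42))


@pytest.fixture(scope="session")
def ten_windows():
    return bc.build_windows(date(2018, 1, 1), date(2024, 1, 1), 18, 6)


@pytest.fixture()
def ideal_record():
    """A record satisfying every packaged ideal criterion."""
    return bc.PatientRecord(
        patient_id="P1",
        surgery_date=date(2019, 5, 14),
        age=58,
        bmi=25.3,
        asa=2,
        albumin=4.0,
        pT_stage="1",
    )


def make_point(label, value, outcome="readmission_3mo", stratum="ideal",
               n=20, defined=True, provisional=False):
    return bc.SeriesPoint(
        window_label=label,
        stratum=bc.Stratum(stratum),
        outcome=outcome,
        n=n,
        value=value,
        defined=defined,
        provisional=provisional,
    )
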