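"""Cohort ingestion and ideal/non-ideal stratification."""

from dataclasses import replace
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import benchcycle as bc
from benchcycle.cohort import PT_STAGES, Predicate, relax_predicate
from benchcycle.errors import ConfigurationError, EmptyCohortError


# ---------------------------------------------------------------- brute-force oracle
def oracle_is_ideal(r: bc.PatientRecord) -> bool:
    """Independent conjunction of the published ideal-patient clauses."""
    if r.albumin is None:
        return False
    return (
        18 <= r.age < 80
        and 20 <= r.bmi < 35
        and r.albumin >= 3.0
        and r.asa < 3
        and not r.smoker
        and not r.anticoagulation
        and not r.bleeding_disorder
        and not r.copd
        and not r.insulin_dependent_diabetes
        and not r.immunosuppression_or_steroids
        and not r.ibd
        and not r.prior_major_abdominal_surgery
        and r.pT_stage in ("0", "is", "1", "2", "3")
        and not r.preop_chemotherapy
    )


record_strategy = st.builds(
    bc.PatientRecord,
    patient_id=st.just("X"),
    surgery_date=st.dates(date(2018, 1, 1), date(2023, 12, 31)),
    age=st.integers(0, 99),
    bmi=st.floats(12.0, 55.0),
    asa=st.integers(0, 5),
    albumin=st.one_of(st.none(), st.floats(1.5, 5.5)),
    smoker=st.booleans(),
    anticoagulation=st.booleans(),
    bleeding_disorder=st.booleans(),
    copd=st.booleans(),
    insulin_dependent_diabetes=st.booleans(),
    immunosuppression_or_steroids=st.booleans(),
    ibd=st.booleans(),
    prior_major_abdominal_surgery=st.booleans(),
    pT_stage=st.sampled_from(PT_STAGES),
    preop_chemotherapy=st.booleans(),
)


class TestClassifyPatient:
    def test_textbook_ideal_patient(self, ideal_record, criteria):
        assert bc.classify_patient(ideal_record, criteria) is bc.Stratum.IDEAL

    @pytest.mark.parametrize(
        "change",
        [
            {"age": 80},  # strict "< 80 years" boundary
            {"smoker": True},
            {"asa": 3},
            {"bmi": 35.0},
            {"bmi": 19.9},
            {"albumin": 2.9},
            {"pT_stage": "4"},
            {"preop_chemotherapy": True},
            {"albumin": None},  # missing criterion field is conservative
        ],
    )
    def test_single_violation_is_non_ideal(self, ideal_record, criteria, change):
        record = replace(ideal_record, **change)
        assert bc.classify_patient(record, criteria) is bc.Stratum.NON_IDEAL

    def test_pt0_and_ptis_count_as_low_stage(self, ideal_record, criteria):
        for stage in ("0", "is"):
            record = replace(ideal_record, pT_stage=stage)
            assert bc.classify_patient(record, criteria) is bc.Stratum.IDEAL

    @settings(derandomize=True, max_examples=500, deadline=None)
    @given(record=record_strategy)
    def test_agrees_with_brute_force_conjunction(self, record, criteria):
        expected = bc.Stratum.IDEAL if oracle_is_ideal(record) else bc.Stratum.NON_IDEAL
        assert bc.classify_patient(record, criteria) is expected

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(record=record_strategy)
    def test_idempotent(self, record, criteria):
        first = bc.classify_patient(record, criteria)
        assert bc.classify_patient(record, criteria) is first

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(record=record_strategy, extra=st.integers(1, 15))
    def test_relaxing_age_bound_is_monotone(self, record, extra, criteria):
        """Loosening one threshold never moves a record out of ideal."""
        before = bc.classify_patient(record, criteria)
        relaxed = relax_predicate(criteria, "age_below_80", 80 + extra)
        after = bc.classify_patient(record, relaxed)
        if before is bc.Stratum.IDEAL:
            assert after is bc.Stratum.IDEAL


class TestStratifyCohort:
    def test_partition_is_disjoint_and_exhaustive(self, default_cohort, criteria):
        ideal, non_ideal = bc.stratify_cohort(default_cohort.records, criteria)
        assert len(ideal) + len(non_ideal) == len(default_cohort.records)
        ids = {r.patient_id for r in ideal} & {r.patient_id for r in non_ideal}
        assert not ids

    def test_order_preserved_within_strata(self, default_cohort, criteria):
        ideal, non_ideal = bc.stratify_cohort(default_cohort.records, criteria)
        order = {r.patient_id: i for i, r in enumerate(default_cohort.records)}
        for group in (ideal, non_ideal):
            positions = [order[r.patient_id] for r in group]
            assert positions == sorted(positions)

    def test_empty_cohort_raises(self, criteria):
        with pytest.raises(EmptyCohortError):
            bc.stratify_cohort([], criteria)

    def test_all_failing_gives_empty_ideal(self, ideal_record, criteria):
        smokers = [replace(ideal_record, smoker=True) for _ in range(5)]
        ideal, non_ideal = bc.stratify_cohort(smokers, criteria)
        assert ideal == [] and len(non_ideal) == 5

    def test_realized_ideal_fraction_near_nominal(self, criteria):
        """Binomial oracle: observed fraction within 3 SE of 16.3%."""
        cohort = bc.generate_cohort(
            bc.CohortScenario(monthly_volume=2000 / 72, ideal_fraction=0.163, seed=5)
        )
        ideal, _ = bc.stratify_cohort(cohort.records, criteria)
        n = len(cohort.records)
        se = (0.163 * 0.837 / n) ** 0.5
        assert abs(len(ideal) / n - 0.163) < 3 * se


class TestLoadCohort:
    def test_roundtrip_count_matches_line_count(self, tmp_path, default_cohort, outcome_specs):
        path = tmp_path / "cohort.csv"
        default_cohort.to_csv(path, ground_truth=False)
        n_lines = len(path.read_text().strip().splitlines()) - 1  # minus header
        records = bc.load_cohort(path, outcome_specs)
        assert len(records) == n_lines == len(default_cohort)

    def test_loaded_records_classify_identically(self, tmp_path, default_cohort,
                                                 outcome_specs, criteria):
        path = tmp_path / "cohort.csv"
        default_cohort.to_csv(path, ground_truth=False)
        records = bc.load_cohort(path, outcome_specs)
        for loaded, truth in zip(records, default_cohort.true_strata):
            assert bc.classify_patient(loaded, criteria) is truth

    def test_missing_required_column_names_it(self, tmp_path, default_cohort, outcome_specs):
        frame = default_cohort.to_frame().drop(columns=["true_stratum", "bmi"])
        path = tmp_path / "bad.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(ConfigurationError, match="bmi"):
            bc.load_cohort(path, outcome_specs)

    def test_empty_file_raises_empty_cohort(self, tmp_path, default_cohort, outcome_specs):
        path = tmp_path / "empty.csv"
        default_cohort.to_frame().drop(columns=["true_stratum"]).head(0).to_csv(
            path, index=False
        )
        with pytest.raises(EmptyCohortError):
            bc.load_cohort(path, outcome_specs)

    def test_unparseable_date_row_rejected_and_reported(self, tmp_path, default_cohort,
                                                        outcome_specs, caplog):
        frame = default_cohort.to_frame().drop(columns=["true_stratum"])
        frame.loc[2, "surgery_date"] = "not-a-date"
        path = tmp_path / "dates.csv"
        frame.to_csv(path, index=False)
        import logging

        with caplog.at_level(logging.WARNING, logger="benchcycle.cohort"):
            records = bc.load_cohort(path, outcome_specs)
        assert len(records) == len(frame) - 1
        assert any("3" in m and "surgery_date" in m for m in caplog.messages)


class TestCriteriaSerialization:
    def test_yaml_roundtrip(self, tmp_path, criteria):
        path = tmp_path / "criteria.yaml"
        criteria.to_yaml(path)
        loaded = bc.CriteriaSet.from_yaml(path)
        assert loaded == criteria

    def test_unknown_comparator_rejected(self):
        with pytest.raises(ConfigurationError):
            Predicate("bad", "age", "approx", 50)
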