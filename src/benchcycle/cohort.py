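"""Patient-level cohort model, CSV ingestion and ideal/non-ideal stratification.

A cohort is a list of :class:`PatientRecord`, one per index operation.
Stratification follows a :class:`CriteriaSet` — an explicit conjunction of
predicates over baseline fields.  The packaged low-anterior-resection (LAR)
criteria implement the published ideal-patient definition: age 18–79,
BMI 20–34.9 kg/m², albumin >= 3.0 g/dL, ASA < 3, pT <= 3 (pT0 and pTis
count as <= 3), and absence of smoking, anticoagulation, bleeding disorder,
COPD, insulin-dependent diabetes, immunosuppression/steroids, IBD, prior
major abdominal surgery and preoperative chemotherapy.  A patient is
*ideal* iff every predicate holds; a missing value on a criterion field is
treated conservatively as non-ideal (with a logged warning), because
"ideal" certifies verified low risk.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml
from dateutil.parser import isoparse

from .errors import ConfigurationError, EmptyCohortError

logger = logging.getLogger(__name__)

PT_STAGES = ("0", "is", "1", "2", "3", "4")

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f"}

#: Baseline columns every cohort CSV must provide.
REQUIRED_COLUMNS = (
    "patient_id",
    "surgery_date",
    "age",
    "bmi",
    "asa",
    "albumin",
    "smoker",
    "anticoagulation",
    "bleeding_disorder",
    "copd",
    "insulin_dependent_diabetes",
    "immunosuppression_or_steroids",
    "ibd",
    "prior_major_abdominal_surgery",
    "pT_stage",
    "preop_chemotherapy",
)

_BOOL_FIELDS = (
    "smoker",
    "anticoagulation",
    "bleeding_disorder",
    "copd",
    "insulin_dependent_diabetes",
    "immunosuppression_or_steroids",
    "ibd",
    "prior_major_abdominal_surgery",
    "preop_chemotherapy",
)


class Stratum(str, Enum):
    """Risk stratum of a patient (or of a whole series)."""

    IDEAL = "ideal"
    NON_IDEAL = "non_ideal"
    OVERALL = "overall"

    def __str__(self) -> str:
        return self.value


class Kind(str, Enum):
    """Measurement kind of an outcome."""

    CONTINUOUS = "continuous"
    BINARY = "binary"

    def __str__(self) -> str:
        return self.value


class Direction(str, Enum):
    """Which side of a benchmark cut-off is 'better'."""

    LOWER_BETTER = "lower_better"
    HIGHER_BETTER = "higher_better"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class OutcomeSpec:
    """Declaration of one monitored outcome.

    Binary outcomes are summarised per window as an event *rate*; continuous
    outcomes as a *median* in their native units.
    """

    name: str
    kind: Kind
    direction: Direction
    units: str = ""

    def __post_init__(self):
        object.__setattr__(self, "kind", Kind(self.kind))
        object.__setattr__(self, "direction", Direction(self.direction))


@dataclass
class PatientRecord:
    """One index operation with baseline criteria fields and outcomes.

    ``continuous_outcomes`` / ``binary_outcomes`` map outcome name to value;
    an explicitly missing value is stored as ``None`` (never silently
    absent once declared in the analysis config).
    """

    patient_id: str
    surgery_date: date
    age: int
    bmi: float
    asa: int
    albumin: Optional[float] = None
    smoker: bool = False
    anticoagulation: bool = False
    bleeding_disorder: bool = False
    copd: bool = False
    insulin_dependent_diabetes: bool = False
    immunosuppression_or_steroids: bool = False
    ibd: bool = False
    prior_major_abdominal_surgery: bool = False
    pT_stage: str = "3"
    preop_chemotherapy: bool = False
    continuous_outcomes: dict = field(default_factory=dict)
    binary_outcomes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.bmi <= 0:
            raise ValueError(f"bmi must be > 0, got {self.bmi}")
        self.pT_stage = str(self.pT_stage)
        if self.pT_stage not in PT_STAGES:
            raise ValueError(
                f"pT_stage must be one of {PT_STAGES}, got {self.pT_stage!r}"
            )

    def outcome_value(self, name: str):
        """Return the value of a named outcome, or None if missing."""
        if name in self.binary_outcomes:
            return self.binary_outcomes[name]
        if name in self.continuous_outcomes:
            return self.continuous_outcomes[name]
        raise KeyError(name)


_OPS = {
    "lt": lambda v, t: v < t,
    "le": lambda v, t: v <= t,
    "ge": lambda v, t: v >= t,
    "gt": lambda v, t: v > t,
    "eq": lambda v, t: v == t,
    "in": lambda v, t: v in t,
}


@dataclass(frozen=True)
class Predicate:
    """A single named criterion: ``record.<field> <op> <value>``."""

    name: str
    field: str
    op: str
    value: object

    def __post_init__(self):
        if self.op not in _OPS:
            raise ConfigurationError(
                f"predicate {self.name!r}: unknown comparator {self.op!r}"
            )

    def holds(self, record: PatientRecord) -> Optional[bool]:
        """True/False, or None when the field value is missing."""
        v = getattr(record, self.field)
        if v is None:
            return None
        if self.op == "in":
            return v in self.value
        return _OPS[self.op](v, self.value)


@dataclass(frozen=True)
class CriteriaSet:
    """Ordered conjunction of predicates defining the 'ideal' stratum."""

    name: str
    predicates: tuple

    def __post_init__(self):
        object.__setattr__(self, "predicates", tuple(self.predicates))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "CriteriaSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc)

    @classmethod
    def _from_doc(cls, doc: Mapping) -> "CriteriaSet":
        preds = []
        for p in doc["criteria"]:
            value = p["value"]
            if isinstance(value, list):
                value = tuple(str(x) if p["field"] == "pT_stage" else x for x in value)
            preds.append(Predicate(p["name"], p["field"], p["op"], value))
        return cls(name=doc.get("name", "criteria"), predicates=tuple(preds))

    def to_yaml(self, path: Union[str, Path]) -> None:
        doc = {
            "name": self.name,
            "criteria": [
                {
                    "name": p.name,
                    "field": p.field,
                    "op": p.op,
                    "value": list(p.value) if isinstance(p.value, tuple) else p.value,
                }
                for p in self.predicates
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def packaged_criteria(name: str = "lar_ideal") -> CriteriaSet:
    """Load a criteria set shipped with the package (default: LAR ideal)."""
    ref = resources.files("benchcycle.data") / f"{name}_criteria.yaml"
    if not ref.is_file():
        raise ConfigurationError(f"no packaged criteria set named {name!r}")
    return CriteriaSet._from_doc(yaml.safe_load(ref.read_text()))


def packaged_outcomes(name: str = "lar") -> list[OutcomeSpec]:
    """Load the outcome declarations shipped with the package."""
    ref = resources.files("benchcycle.data") / f"{name}_outcomes.yaml"
    if not ref.is_file():
        raise ConfigurationError(f"no packaged outcome set named {name!r}")
    doc = yaml.safe_load(ref.read_text())
    return [OutcomeSpec(**o) for o in doc["outcomes"]]


def classify_patient(record: PatientRecord, criteria: CriteriaSet) -> Stratum:
    """Assign a record to the ideal or non-ideal stratum.

    Ideal iff every predicate of ``criteria`` holds.  A missing value on any
    criterion field yields non-ideal with a logged warning (conservative:
    'ideal' denotes verified low risk).  Classification of one record never
    depends on other records, and is deterministic.
    """
    for pred in criteria.predicates:
        ok = pred.holds(record)
        if ok is None:
            logger.warning(
                "patient %s: missing value for criterion %r (field %s); "
                "classified non_ideal",
                record.patient_id,
                pred.name,
                pred.field,
            )
            return Stratum.NON_IDEAL
        if not ok:
            return Stratum.NON_IDEAL
    return Stratum.IDEAL


def stratify_cohort(
    records: Sequence[PatientRecord], criteria: CriteriaSet
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Partition a cohort into (ideal, non_ideal) lists, order preserved."""
    if not records:
        raise EmptyCohortError("cannot stratify an empty cohort")
    ideal, non_ideal = [], []
    for r in records:
        (ideal if classify_patient(r, criteria) is Stratum.IDEAL else non_ideal).append(r)
    return ideal, non_ideal


def _parse_bool(raw: str, column: str, row: int) -> Optional[bool]:
    s = raw.strip().lower()
    if s == "":
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ConfigurationError(
        f"row {row}: cannot parse boolean column {column!r} value {raw!r}"
    )


def _parse_float(raw: str) -> Optional[float]:
    s = raw.strip()
    return float(s) if s else None


def load_cohort(
    path: Union[str, Path], outcome_specs: Iterable[OutcomeSpec]
) -> list[PatientRecord]:
    """Read a cohort CSV into PatientRecords.

    The file must be comma-separated UTF-8 with ISO-8601 surgery dates and
    contain every baseline column plus one column per declared outcome.
    Boolean columns accept 0/1/true/false/yes/no (case-insensitive); empty
    cells are explicit missing values.  Rows whose surgery_date cannot be
    parsed are rejected, with the offending row indices reported in a
    warning.

    Raises
    ------
    ConfigurationError
        If a required or declared outcome column is absent from the header.
    EmptyCohortError
        If the file contains no data rows.
    """
    outcome_specs = list(outcome_specs)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in REQUIRED_COLUMNS:
            if col not in header:
                raise ConfigurationError(f"cohort file is missing required column {col!r}")
        for spec in outcome_specs:
            if spec.name not in header:
                raise ConfigurationError(
                    f"cohort file is missing declared outcome column {spec.name!r}"
                )
        records: list[PatientRecord] = []
        bad_rows: list[int] = []
        n_rows = 0
        for i, row in enumerate(reader, start=1):
            n_rows += 1
            try:
                sdate = isoparse(row["surgery_date"].strip()).date()
            except (ValueError, TypeError):
                bad_rows.append(i)
                continue
            kwargs = dict(
                patient_id=row["patient_id"].strip(),
                surgery_date=sdate,
                age=int(float(row["age"])),
                bmi=float(row["bmi"]),
                asa=int(float(row["asa"])),
                albumin=_parse_float(row["albumin"]),
                pT_stage=row["pT_stage"].strip(),
            )
            for col in _BOOL_FIELDS:
                kwargs[col] = _parse_bool(row[col], col, i)
            cont, binary = {}, {}
            for spec in outcome_specs:
                raw = row[spec.name]
                if spec.kind is Kind.BINARY:
                    binary[spec.name] = _parse_bool(raw, spec.name, i)
                else:
                    cont[spec.name] = _parse_float(raw)
            records.append(
                PatientRecord(**kwargs, continuous_outcomes=cont, binary_outcomes=binary)
            )
    if n_rows == 0:
        raise EmptyCohortError(f"cohort file {path} contains no data rows")
    if bad_rows:
        logger.warning(
            "rejected %d row(s) with unparseable surgery_date: rows %s",
            len(bad_rows),
            bad_rows,
        )
    logger.info("loaded %d of %d records from %s", len(records), n_rows, path)
    return records


def relax_predicate(criteria: CriteriaSet, name: str, new_value) -> CriteriaSet:
    """Return a copy of ``criteria`` with one predicate's threshold replaced.

    Used to probe monotonicity: relaxing any single criterion can only move
    records from non-ideal toward ideal, never the reverse.
    """
    preds = tuple(
        replace(p, value=new_value) if p.name == name else p for p in criteria.predicates
    )
    if preds == criteria.predicates and all(p.name != name for p in criteria.predicates):
        raise KeyError(name)
    return replace(criteria, predicates=preds)
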