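"""Model/results interface for one benchmarking improvement-cycle analysis.

:class:`BenchmarkCycle` is built from a cohort (records, a DataFrame or a
CSV file) together with a benchmark registry, an ideal-patient criteria
set and the window configuration.  Calling :meth:`BenchmarkCycle.fit` runs
the computational steps of the improvement cycle — stratify, window,
summarise, compare, flag — and returns a :class:`CycleResults` holding the
moving median/rate series, the per-period deviation flags, the
consecutive-run signals and a text summary, with plotting and export
hanging off the results object::

    model = BenchmarkCycle.from_csv("cohort.csv")
    res = model.fit()
    print(res.summary())
    res.plot("readmission_3mo", "ideal", path="readmission_ideal.png")
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import plotting
from .benchmark import BenchmarkRegistry, FlagReport, evaluate, load_registry
from .cohort import (
    CriteriaSet,
    Kind,
    OutcomeSpec,
    PatientRecord,
    Stratum,
    classify_patient,
    load_cohort,
    packaged_criteria,
    packaged_outcomes,
    stratify_cohort,
)
from .errors import ConfigurationError, EmptyCohortError, RegistryKeyError
from .windows import SeriesPoint, Window, build_windows, compute_series, series_to_frame

logger = logging.getLogger(__name__)

_ANALYSIS_STRATA = (Stratum.IDEAL, Stratum.NON_IDEAL)


@dataclass
class BenchmarkCycle:
    """One cohort x registry x window-scheme benchmarking analysis.

    Parameters
    ----------
    records
        Patient-level records of index operations.
    registry
        Benchmark cut-offs; defaults to the packaged published LAR values.
    criteria
        Ideal-patient definition; defaults to the packaged LAR criteria.
    outcomes
        Outcomes to analyse.  Each must be present on the cohort records
        and have at least one registry entry.
    study_start, study_end
        Half-open study period; defaults to the span of surgery dates
        rounded outward to whole months... actually to the exact min/max
        surgery dates, so pass explicit dates for calendar-aligned windows.
    length_months, step_months
        Rolling-window geometry (default 18-month windows every 6 months).
    k
        Run-rule length: a signal needs >= k consecutive deviating periods.
    follow_up_months, analysis_date
        Windows whose end plus the follow-up horizon exceeds the analysis
        date are marked provisional (outcome ascertainment incomplete).
    min_n
        Minimum patients per window for a defined series point.
    """

    records: Sequence[PatientRecord]
    registry: BenchmarkRegistry = None
    criteria: CriteriaSet = None
    outcomes: Sequence[OutcomeSpec] = None
    study_start: date = None
    study_end: date = None
    length_months: int = 18
    step_months: int = 6
    k: int = 2
    follow_up_months: int = 6
    analysis_date: Optional[date] = None
    min_n: int = 1
    procedure: str = "LAR"
    include_overall: bool = False

    def __post_init__(self):
        self.records = list(self.records)
        if not self.records:
            raise EmptyCohortError("BenchmarkCycle requires a nonempty cohort")
        if self.registry is None:
            self.registry = load_registry("lar_2022")
        if self.criteria is None:
            self.criteria = packaged_criteria("lar_ideal")
        if self.outcomes is None:
            self.outcomes = [
                spec
                for spec in packaged_outcomes()
                if self._in_registry(spec.name) and self._on_records(spec.name)
            ]
        self.outcomes = list(self.outcomes)
        if self.study_start is None:
            self.study_start = min(r.surgery_date for r in self.records)
        if self.study_end is None:
            # day after the last operation, so the last record is inside
            self.study_end = max(r.surgery_date for r in self.records) + timedelta(days=1)
        self._validate_outcomes()

    def _in_registry(self, outcome: str) -> bool:
        for stratum in _ANALYSIS_STRATA:
            try:
                self.registry.get(self.procedure, outcome, stratum)
                return True
            except RegistryKeyError:
                continue
        return False

    def _on_records(self, outcome: str) -> bool:
        r = self.records[0]
        return outcome in r.binary_outcomes or outcome in r.continuous_outcomes

    def _validate_outcomes(self) -> None:
        for spec in self.outcomes:
            if not self._on_records(spec.name):
                raise ConfigurationError(
                    f"outcome {spec.name!r} is not present on the cohort records"
                )
            if not self._in_registry(spec.name):
                raise ConfigurationError(
                    f"outcome {spec.name!r} has no {self.procedure} registry entry"
                )

    # ---------------------------------------------------------------- constructors
    @classmethod
    def from_csv(
        cls,
        path: Union[str, Path],
        outcomes: Optional[Sequence[OutcomeSpec]] = None,
        **kwargs,
    ) -> "BenchmarkCycle":
        """Build a model from a cohort CSV file."""
        if outcomes is None:
            outcomes = packaged_outcomes()
            registry = kwargs.get("registry") or load_registry("lar_2022")
            procedure = kwargs.get("procedure", "LAR")
            outcomes = [
                spec
                for spec in outcomes
                if any(
                    _has_entry(registry, procedure, spec.name, s) for s in _ANALYSIS_STRATA
                )
            ]
            kwargs.setdefault("registry", registry)
        records = load_cohort(path, outcomes)
        return cls(records=records, outcomes=list(outcomes), **kwargs)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, outcomes: Sequence[OutcomeSpec], **kwargs
    ) -> "BenchmarkCycle":
        """Build a model from a tidy cohort DataFrame (CSV schema columns)."""
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            frame.to_csv(fh, index=False)
            tmp = fh.name
        try:
            records = load_cohort(tmp, outcomes)
        finally:
            Path(tmp).unlink(missing_ok=True)
        return cls(records=records, outcomes=list(outcomes), **kwargs)

    # ---------------------------------------------------------------- fitting
    def fit(self) -> "CycleResults":
        """Run stratification, windowing, comparison and flagging."""
        windows = build_windows(
            self.study_start, self.study_end, self.length_months, self.step_months
        )
        ideal, non_ideal = stratify_cohort(self.records, self.criteria)
        by_stratum = {
            Stratum.IDEAL: ideal,
            Stratum.NON_IDEAL: non_ideal,
            Stratum.OVERALL: list(self.records),
        }
        series: dict[tuple[str, Stratum], list[SeriesPoint]] = {}
        reports: dict[tuple[str, Stratum], FlagReport] = {}
        strata = list(_ANALYSIS_STRATA) + ([Stratum.OVERALL] if self.include_overall else [])
        for spec in self.outcomes:
            for stratum in strata:
                pts = compute_series(
                    by_stratum[stratum],
                    windows,
                    spec,
                    stratum,
                    min_n=self.min_n,
                    analysis_date=self.analysis_date,
                    follow_up_months=self.follow_up_months,
                )
                series[(spec.name, stratum)] = pts
                if stratum is Stratum.OVERALL:
                    continue
                try:
                    self.registry.get(self.procedure, spec.name, stratum)
                except RegistryKeyError:
                    logger.info(
                        "no %s benchmark for %s/%s; series computed, not flagged",
                        self.procedure,
                        spec.name,
                        stratum,
                    )
                    continue
                reports[(spec.name, stratum)] = evaluate(
                    pts, self.registry, k=self.k, procedure=self.procedure
                )
        return CycleResults(
            model=self,
            windows=windows,
            series=series,
            flag_reports=reports,
            n_ideal=len(ideal),
            n_non_ideal=len(non_ideal),
        )


def _has_entry(registry, procedure, outcome, stratum) -> bool:
    try:
        registry.get(procedure, outcome, stratum)
        return True
    except RegistryKeyError:
        return False


@dataclass
class CycleResults:
    """Results of one fitted benchmarking cycle."""

    model: BenchmarkCycle
    windows: list
    series: dict
    flag_reports: dict
    n_ideal: int
    n_non_ideal: int

    @property
    def any_signal(self) -> bool:
        """True iff any outcome x stratum fired a consecutive-run signal."""
        return any(r.any_signal for r in self.flag_reports.values())

    @property
    def signals(self) -> dict:
        """Non-empty signal lists keyed by (outcome, stratum)."""
        return {
            key: report.signals
            for key, report in self.flag_reports.items()
            if report.signals
        }

    def series_frame(self) -> pd.DataFrame:
        """All series as one tidy frame (window, stratum, outcome, n, value)."""
        frames = [series_to_frame(pts, self.windows) for pts in self.series.values()]
        return pd.concat(frames, ignore_index=True)

    def flags_frame(self) -> pd.DataFrame:
        """All per-period flags as one tidy frame."""
        frames = [r.to_frame() for r in self.flag_reports.values()]
        return pd.concat(frames, ignore_index=True)

    def plot(
        self,
        outcome: str,
        stratum: Union[Stratum, str],
        path: Optional[Union[str, Path]] = None,
    ):
        """Benchmark comparison plot for one outcome x stratum series."""
        stratum = Stratum(stratum)
        pts = self.series[(outcome, stratum)]
        entry = self.model.registry.get(self.model.procedure, outcome, stratum)
        report = self.flag_reports.get((outcome, stratum))
        return plotting.render_plot(pts, self.windows, entry, report, path=path)

    def export(self, outdir: Union[str, Path]) -> dict:
        """Write series CSVs and flag-report JSONs; returns written paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = {"series": [], "flags": []}
        for (outcome, stratum), pts in self.series.items():
            p = outdir / f"series_{outcome}_{stratum}.csv"
            series_to_frame(pts, self.windows).to_csv(p, index=False, lineterminator="\n")
            written["series"].append(p)
        for (outcome, stratum), report in self.flag_reports.items():
            p = outdir / f"flags_{outcome}_{stratum}.json"
            report.to_json(p)
            written["flags"].append(p)
        return written

    def summary(self) -> str:
        """Plain-text summary table in the style of a model results object."""
        m = self.model
        lines = []
        title = "Benchmark improvement-cycle results"
        lines.append(title)
        lines.append("=" * 78)
        lines.append(f"Procedure:        {m.procedure:<12}  Windows: {len(self.windows)}"
                     f" x {m.length_months} months, step {m.step_months}")
        lines.append(
            f"Cohort:           {len(m.records)} operations "
            f"({self.n_ideal} ideal, {self.n_non_ideal} non-ideal)"
        )
        lines.append(
            f"Study period:     [{m.study_start.isoformat()}, {m.study_end.isoformat()})"
            f"    run-rule k = {m.k}"
        )
        lines.append("-" * 78)
        lines.append(
            f"{'outcome':<22}{'stratum':<11}{'cutoff':>8}{'windows':>9}"
            f"{'deviations':>12}{'signals':>9}"
        )
        for (outcome, stratum), report in sorted(
            self.flag_reports.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
        ):
            entry = m.registry.get(m.procedure, outcome, stratum)
            n_def = len(report.entries)
            lines.append(
                f"{outcome:<22}{str(stratum):<11}{entry.cutoff:>8.1f}{n_def:>9}"
                f"{report.n_deviations:>12}{len(report.signals):>9}"
            )
        lines.append("-" * 78)
        if self.any_signal:
            lines.append("Signals (runs of >= k consecutive deviating periods):")
            for (outcome, stratum), sigs in sorted(
                self.signals.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))
            ):
                for s in sigs:
                    lines.append(
                        f"  {outcome} [{stratum}]: {s.start_label}-{s.end_label} "
                        f"(run of {s.run_length})"
                    )
        else:
            lines.append("No signals: all series within benchmark run-rule limits.")
        lines.append("=" * 78)
        return "\n".join(lines)
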