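"""Benchmark registry, deviation flagging and consecutive-run signal rules.

A benchmark cut-off is the 75th percentile of all reference-centre medians
of an outcome for lower-is-better outcomes (25th for higher-is-better): the
best achievable quartile of centre performance.  The accompanying *range*
is the span of centre medians and serves as display context only — it is
never flagged on by itself.

A single period whose statistic lies strictly on the worse side of the
cut-off is a *deviation*; meeting the cut-off exactly is compliant, since
cut-offs mark achievable best-quartile performance.  A run of at least
``k`` consecutive deviating periods is a *signal* warranting case review —
a simple run rule in the spirit of statistical process control, used here
instead of control limits, which the benchmarking context does not define.

Rates are stored and compared in percentage points, matching the published
registry values; series points carry rates in [0, 1] and are scaled at
comparison time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .cohort import Direction, Stratum
from .errors import ConfigurationError, RegistryKeyError
from .windows import SeriesPoint

#: Quantile convention for derive_benchmark: linear interpolation between
#: order statistics (numpy's default).  Overridable per call.
DEFAULT_QUANTILE_METHOD = "linear"


@dataclass(frozen=True)
class BenchmarkEntry:
    """Published cut-off and reference-centre range for one outcome/stratum.

    ``cutoff``, ``range_low`` and ``range_high`` are in percentage points
    for rate outcomes (units "%") or native outcome units for continuous
    outcomes.
    """

    procedure: str
    outcome: str
    stratum: Stratum
    cutoff: float
    range_low: float
    range_high: float
    direction: Direction
    units: str = ""
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "stratum", Stratum(self.stratum))
        object.__setattr__(self, "direction", Direction(self.direction))
        if not (self.range_low <= self.cutoff <= self.range_high):
            raise ConfigurationError(
                f"{self.procedure}/{self.outcome}/{self.stratum}: cutoff "
                f"{self.cutoff} outside range [{self.range_low}, {self.range_high}]"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.procedure, self.outcome, str(self.stratum))


class BenchmarkRegistry:
    """Lookup table of BenchmarkEntry keyed by (procedure, outcome, stratum)."""

    def __init__(self, entries: Sequence[BenchmarkEntry], name: str = "registry"):
        self.name = name
        self._entries: dict[tuple, BenchmarkEntry] = {}
        for e in entries:
            if e.key in self._entries:
                raise ConfigurationError(f"duplicate registry key {e.key}")
            self._entries[e.key] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def get(
        self, procedure: str, outcome: str, stratum: Union[Stratum, str]
    ) -> BenchmarkEntry:
        key = (procedure, outcome, str(Stratum(stratum)))
        try:
            return self._entries[key]
        except KeyError:
            raise RegistryKeyError(*key) from None

    def to_yaml(self, path: Union[str, Path]) -> None:
        doc = {
            "name": self.name,
            "entries": [
                {
                    "procedure": e.procedure,
                    "outcome": e.outcome,
                    "stratum": str(e.stratum),
                    "cutoff": e.cutoff,
                    "range_low": e.range_low,
                    "range_high": e.range_high,
                    "direction": str(e.direction),
                    "units": e.units,
                    "source": e.source,
                }
                for e in self
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _registry_from_doc(doc) -> BenchmarkRegistry:
    entries = [BenchmarkEntry(**e) for e in doc["entries"]]
    return BenchmarkRegistry(entries, name=doc.get("name", "registry"))


def load_registry(path_or_name: Union[str, Path] = "lar_2022") -> BenchmarkRegistry:
    """Load a benchmark registry from a YAML file or a packaged name.

    The packaged ``lar_2022`` registry transcribes the published LAR
    cut-offs (anastomotic leak, lymph-node yield >= 12, CDC >= 3a at
    discharge, 3-month readmission, per stratum).
    """
    p = Path(path_or_name)
    if p.is_file():
        with open(p) as fh:
            return _registry_from_doc(yaml.safe_load(fh))
    ref = resources.files("benchcycle.data") / f"{path_or_name}_registry.yaml"
    if ref.is_file():
        return _registry_from_doc(yaml.safe_load(ref.read_text()))
    raise ConfigurationError(f"no registry file or packaged registry {path_or_name!r}")


def derive_benchmark(
    centre_medians: Sequence[float],
    direction: Union[Direction, str],
    procedure: str = "custom",
    outcome: str = "outcome",
    stratum: Union[Stratum, str] = Stratum.IDEAL,
    units: str = "",
    source: str = "derived from centre medians",
    quantile_method: str = DEFAULT_QUANTILE_METHOD,
) -> BenchmarkEntry:
    """Derive a benchmark entry from per-centre median outcome values.

    The cut-off is the 75th percentile of the centre medians when lower is
    better and the 25th when higher is better; the range is their min/max.
    The percentile uses linear interpolation between order statistics by
    default (``quantile_method`` accepts any numpy convention).
    """
    medians = [float(m) for m in centre_medians]
    if len(medians) < 2:
        raise ConfigurationError("derive_benchmark requires at least 2 centre medians")
    direction = Direction(direction)
    q = 75 if direction is Direction.LOWER_BETTER else 25
    cutoff = float(np.percentile(medians, q, method=quantile_method))
    return BenchmarkEntry(
        procedure=procedure,
        outcome=outcome,
        stratum=Stratum(stratum),
        cutoff=cutoff,
        range_low=min(medians),
        range_high=max(medians),
        direction=direction,
        units=units,
        source=source,
    )


def _scaled_value(point: SeriesPoint, entry: BenchmarkEntry) -> float:
    # registry rates are in percentage points; series rates live in [0, 1]
    return point.value * 100.0 if entry.units == "%" else point.value


def flag_deviation(point: SeriesPoint, entry: BenchmarkEntry) -> tuple[bool, float]:
    """Compare one defined series point against its benchmark entry.

    Returns ``(deviation, magnitude)`` where magnitude is the value minus
    the cut-off signed toward 'worse' (positive iff deviating or exactly
    how far inside the benchmark, negated, otherwise).  Equality is never
    a deviation.

    Raises
    ------
    RegistryKeyError
        If the point's outcome or stratum does not match the entry.
    ValueError
        If the point is undefined.
    """
    if point.outcome != entry.outcome or Stratum(point.stratum) != entry.stratum:
        raise RegistryKeyError(entry.procedure, point.outcome, str(point.stratum))
    if not point.defined or point.value is None:
        raise ValueError(f"cannot flag undefined point {point.window_label}")
    value = _scaled_value(point, entry)
    if entry.direction is Direction.LOWER_BETTER:
        magnitude = value - entry.cutoff
    else:
        magnitude = entry.cutoff - value
    return magnitude > 0, magnitude


@dataclass(frozen=True)
class Signal:
    """A maximal run of >= k consecutive deviating periods."""

    start_label: str
    end_label: str
    run_length: int


@dataclass(frozen=True)
class PeriodFlag:
    """Deviation status of one defined period."""

    window_label: str
    value: float  # in registry units (percentage points for rates)
    cutoff: float
    deviation: bool
    deviation_magnitude: float


@dataclass
class FlagReport:
    """Per-period deviations and consecutive-run signals for one series."""

    procedure: str
    outcome: str
    stratum: Stratum
    k: int
    entries: list = field(default_factory=list)
    signals: list = field(default_factory=list)

    @property
    def any_signal(self) -> bool:
        return bool(self.signals)

    @property
    def n_deviations(self) -> int:
        return sum(e.deviation for e in self.entries)

    def to_dict(self) -> dict:
        return {
            "procedure": self.procedure,
            "outcome": self.outcome,
            "stratum": str(self.stratum),
            "k": self.k,
            "entries": [
                {
                    "window_label": e.window_label,
                    "value": e.value,
                    "cutoff": e.cutoff,
                    "deviation": e.deviation,
                    "deviation_magnitude": e.deviation_magnitude,
                }
                for e in self.entries
            ],
            "signals": [
                {
                    "start_label": s.start_label,
                    "end_label": s.end_label,
                    "run_length": s.run_length,
                }
                for s in self.signals
            ],
        }

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, doc: dict) -> "FlagReport":
        report = cls(
            procedure=doc["procedure"],
            outcome=doc["outcome"],
            stratum=Stratum(doc["stratum"]),
            k=doc["k"],
        )
        report.entries = [PeriodFlag(**e) for e in doc["entries"]]
        report.signals = [Signal(**s) for s in doc["signals"]]
        return report

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "FlagReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "outcome": self.outcome,
                    "stratum": str(self.stratum),
                    "window_label": e.window_label,
                    "value": e.value,
                    "cutoff": e.cutoff,
                    "deviation": e.deviation,
                    "deviation_magnitude": e.deviation_magnitude,
                }
                for e in self.entries
            ]
        )


def run_rule(deviations: Sequence[bool], k: int) -> list[tuple[int, int]]:
    """Find all maximal runs of >= k consecutive deviations.

    Returns runs as (start_index, end_index) inclusive pairs over the input
    order.  With k = 1 this is simply every maximal run of True values.
    """
    if k < 1:
        raise ConfigurationError("run-rule k must be >= 1")
    runs: list[tuple[int, int]] = []
    start: Optional[int] = None
    for i, d in enumerate(deviations):
        if d and start is None:
            start = i
        elif not d and start is not None:
            if i - start >= k:
                runs.append((start, i - 1))
            start = None
    if start is not None and len(deviations) - start >= k:
        runs.append((start, len(deviations) - 1))
    return runs


def evaluate(
    series: Sequence[SeriesPoint],
    registry: BenchmarkRegistry,
    k: int = 2,
    procedure: str = "LAR",
) -> FlagReport:
    """Build the full flag report for one outcome x stratum series.

    Each defined point is compared to its registry entry; undefined points
    carry no flag and *break* runs — a signal cannot span a window where
    the statistic could not be computed.
    """
    if not series:
        raise ConfigurationError("evaluate requires a nonempty series")
    outcome = series[0].outcome
    stratum = Stratum(series[0].stratum)
    entry = registry.get(procedure, outcome, stratum)
    report = FlagReport(procedure=procedure, outcome=outcome, stratum=stratum, k=k)

    # deviation per window; None marks undefined points (run breakers)
    dev_by_window: list[tuple[str, Optional[bool]]] = []
    for p in series:
        if not p.defined:
            dev_by_window.append((p.window_label, None))
            continue
        deviation, magnitude = flag_deviation(p, entry)
        report.entries.append(
            PeriodFlag(
                window_label=p.window_label,
                value=_scaled_value(p, entry),
                cutoff=entry.cutoff,
                deviation=deviation,
                deviation_magnitude=magnitude,
            )
        )
        dev_by_window.append((p.window_label, deviation))

    # scan contiguous defined segments independently so undefined points break runs
    segment: list[tuple[str, bool]] = []
    segments: list[list[tuple[str, bool]]] = []
    for label, dev in dev_by_window:
        if dev is None:
            if segment:
                segments.append(segment)
                segment = []
        else:
            segment.append((label, dev))
    if segment:
        segments.append(segment)
    for seg in segments:
        flags = [d for _, d in seg]
        for start, end in run_rule(flags, k):
            report.signals.append(
                Signal(
                    start_label=seg[start][0],
                    end_label=seg[end][0],
                    run_length=end - start + 1,
                )
            )
    return report
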