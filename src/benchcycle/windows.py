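"""Overlapping rolling time windows and per-window moving statistics.

The monitoring scheme evaluates outcomes over overlapping 18-month windows
advanced in 6-month steps (both configurable), so each window pools enough
patients for a stable statistic while the half-yearly step keeps the series
responsive.  Continuous outcomes are summarised per window by their median
(the *moving median*); binary outcomes by the event proportion (the
*moving rate*).

Windows are half-open calendar intervals ``[start, start + length_months)``
built with exact month arithmetic, so 6-month steps never drift.  Window
membership keys on the surgery date of the index operation: outcomes are
attributes of the index procedure, whatever date they occur on.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from datetime import date
from typing import Optional, Sequence, Union

import pandas as pd
from dateutil.relativedelta import relativedelta

from .cohort import Kind, OutcomeSpec, PatientRecord, Stratum
from .errors import ConfigurationError, DataIntegrityError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """One rolling analysis period, a half-open interval [start, end)."""

    label: str
    start: date
    end: date
    length_months: int
    step_months: int

    def contains(self, d: date) -> bool:
        return self.start <= d < self.end


@dataclass(frozen=True)
class SeriesPoint:
    """The per-window statistic for one outcome in one stratum.

    ``value`` is the median in outcome units for continuous outcomes, or a
    rate in [0, 1] for binary outcomes; ``defined`` is False (and ``value``
    None) when fewer than the reporting minimum of patients contribute.
    ``provisional`` marks windows whose follow-up horizon extends past the
    analysis date, i.e. outcome ascertainment may still be incomplete.
    """

    window_label: str
    stratum: Stratum
    outcome: str
    n: int
    value: Optional[float]
    defined: bool
    provisional: bool = False


def _months_between(start: date, end: date) -> int:
    """Whole calendar months from start to end (end >= start)."""
    delta = relativedelta(end, start)
    return delta.years * 12 + delta.months


def build_windows(
    study_start: date,
    study_end: date,
    length_months: int = 18,
    step_months: int = 6,
) -> list[Window]:
    """Build the overlapping rolling windows covering a study period.

    Windows start at ``study_start + i * step_months`` and run
    ``length_months``; only windows ending on or before ``study_end`` are
    produced, so the count is ``floor((span - length) / step) + 1``.
    Labels are p1, p2, ... in start order.

    Raises
    ------
    ConfigurationError
        If the study span is shorter than one window, or steps/lengths are
        non-positive.
    """
    if study_end <= study_start:
        raise ConfigurationError("study_end must be after study_start")
    if length_months < 1 or step_months < 1:
        raise ConfigurationError("length_months and step_months must be >= 1")
    span = _months_between(study_start, study_end)
    if span < length_months:
        raise ConfigurationError(
            f"study span of {span} months is shorter than one "
            f"{length_months}-month window"
        )
    windows = []
    i = 0
    while True:
        start = study_start + relativedelta(months=i * step_months)
        end = start + relativedelta(months=length_months)
        if end > study_end:
            break
        windows.append(
            Window(
                label=f"p{i + 1}",
                start=start,
                end=end,
                length_months=length_months,
                step_months=step_months,
            )
        )
        i += 1
    return windows


def assign_to_windows(
    records: Sequence[PatientRecord], windows: Sequence[Window]
) -> dict[str, list[PatientRecord]]:
    """Map each window label to the records operated within it.

    A record belongs to window w iff ``w.start <= surgery_date < w.end``;
    because windows overlap, a record typically belongs to
    length/step consecutive windows.
    """
    out: dict[str, list[PatientRecord]] = {w.label: [] for w in windows}
    for r in records:
        for w in windows:
            if w.contains(r.surgery_date):
                out[w.label].append(r)
    return out


def window_median(values: Sequence[float]) -> float:
    """Sample median; even counts average the two middle order statistics."""
    if not values:
        raise ValueError("window_median requires a nonempty list")
    return statistics.median(values)


def window_rate(events: int, n: int) -> Optional[float]:
    """Event proportion in [0, 1]; None for an empty window (n = 0)."""
    if events < 0 or n < 0:
        raise DataIntegrityError("counts must be non-negative")
    if events > n:
        raise DataIntegrityError(f"events ({events}) exceeds n ({n})")
    if n == 0:
        return None
    return events / n


def compute_series(
    records: Sequence[PatientRecord],
    windows: Sequence[Window],
    outcome: OutcomeSpec,
    stratum: Union[Stratum, str],
    min_n: int = 1,
    analysis_date: Optional[date] = None,
    follow_up_months: int = 6,
) -> list[SeriesPoint]:
    """Compute the moving median/rate series for one outcome and stratum.

    ``records`` must already be restricted to the requested stratum (or be
    the whole cohort for ``overall``).  Records with a missing value for
    the outcome are excluded from that point's n, with the exclusion count
    logged.  Points with fewer than ``min_n`` contributing patients are
    undefined rather than zero.  When ``analysis_date`` is given, windows
    whose end plus the follow-up horizon exceeds it are flagged
    provisional.
    """
    stratum = Stratum(stratum)
    membership = assign_to_windows(records, windows)
    points: list[SeriesPoint] = []
    n_missing_total = 0
    for w in windows:
        members = membership[w.label]
        try:
            values = [m.outcome_value(outcome.name) for m in members]
        except KeyError:
            raise ConfigurationError(
                f"outcome {outcome.name!r} not present on cohort records"
            ) from None
        present = [v for v in values if v is not None]
        n_missing_total += len(values) - len(present)
        n = len(present)
        provisional = bool(
            analysis_date is not None
            and w.end + relativedelta(months=follow_up_months) > analysis_date
        )
        if n < min_n or n == 0:
            points.append(
                SeriesPoint(w.label, stratum, outcome.name, n, None, False, provisional)
            )
            continue
        if outcome.kind is Kind.BINARY:
            value = window_rate(sum(bool(v) for v in present), n)
        else:
            value = window_median([float(v) for v in present])
        points.append(
            SeriesPoint(w.label, stratum, outcome.name, n, value, True, provisional)
        )
    if n_missing_total:
        logger.info(
            "outcome %s (%s): %d record-window pairs excluded for missing values",
            outcome.name,
            stratum,
            n_missing_total,
        )
    return points


def series_to_frame(
    points: Sequence[SeriesPoint], windows: Sequence[Window]
) -> pd.DataFrame:
    """Tidy export of a series: one row per window point."""
    by_label = {w.label: w for w in windows}
    rows = [
        {
            "window_label": p.window_label,
            "start": by_label[p.window_label].start.isoformat(),
            "end": by_label[p.window_label].end.isoformat(),
            "stratum": str(p.stratum),
            "outcome": p.outcome,
            "n": p.n,
            "value": p.value,
            "defined": p.defined,
            "provisional": p.provisional,
        }
        for p in points
    ]
    return pd.DataFrame(rows)
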