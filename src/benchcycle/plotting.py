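"""Benchmark comparison plots.

One panel per outcome x stratum: the moving median/rate series as a line
with markers over window labels p1..pN, the benchmark cut-off as a solid
horizontal line, the span of reference-centre medians as dotted lines,
deviating periods marked, and provisional windows (incomplete follow-up)
shaded.  Rendering is deterministic for fixed inputs so repeated runs of
the same analysis produce identical image files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt

from .benchmark import BenchmarkEntry, FlagReport
from .cohort import Direction
from .windows import SeriesPoint, Window

logger = logging.getLogger(__name__)


def render_plot(
    points: Sequence[SeriesPoint],
    windows: Sequence[Window],
    entry: BenchmarkEntry,
    report: Optional[FlagReport] = None,
    path: Optional[Union[str, Path]] = None,
):
    """Render one benchmark comparison panel; returns the Figure.

    ``points`` must all belong to the entry's outcome and stratum.  Rates
    are drawn in percentage points to match the registry scale.  Returns
    None (with a warning) when no point in the series is defined.
    """
    defined = [p for p in points if p.defined]
    if not defined:
        logger.warning(
            "all points undefined for %s/%s; skipping plot", entry.outcome, entry.stratum
        )
        return None

    scale = 100.0 if entry.units == "%" else 1.0
    labels = [p.window_label for p in points]
    xs = range(len(points))
    x_def = [i for i, p in enumerate(points) if p.defined]
    y_def = [p.value * scale for p in points if p.defined]

    fig, ax = plt.subplots(figsize=(7.0, 4.0), dpi=150)
    ax.axhline(entry.cutoff, color="0.2", lw=1.6, label=f"benchmark ({entry.cutoff:g})")
    ax.axhline(entry.range_low, color="0.5", lw=1.0, ls=":", label="centre-median range")
    ax.axhline(entry.range_high, color="0.5", lw=1.0, ls=":")
    ax.plot(x_def, y_def, "-o", color="black", ms=5, lw=1.4, label="own results")

    deviating = {e.window_label for e in report.entries if e.deviation} if report else set()
    dev_x = [i for i, p in enumerate(points) if p.window_label in deviating]
    dev_y = [points[i].value * scale for i in dev_x]
    if dev_x:
        ax.plot(dev_x, dev_y, "o", color="crimson", ms=9, mfc="none", mew=1.8,
                label="deviation")

    for i, p in enumerate(points):
        if p.provisional:
            ax.axvspan(i - 0.4, i + 0.4, color="0.85", zorder=0,
                       hatch="//", alpha=0.5, lw=0)

    ax.set_xticks(list(xs))
    ax.set_xticklabels(labels)
    ax.set_xlabel("rolling period")
    unit = entry.units or "value"
    better = "lower" if entry.direction is Direction.LOWER_BETTER else "higher"
    ax.set_ylabel(f"{entry.outcome} ({unit}, {better} is better)")
    ax.set_title(f"{entry.procedure}: {entry.outcome}, {entry.stratum} patients")
    ax.legend(loc="best", fontsize=8, frameon=False)
    fig.tight_layout()

    if path is not None:
        path = Path(path)
        kwargs = {"metadata": {"Date": None}} if path.suffix == ".svg" else {}
        fig.savefig(path, **kwargs)
        plt.close(fig)
    return fig
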