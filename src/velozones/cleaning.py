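"""GPS data-cleaning rules: point-level spike removal, file-level exclusion.

Two rules, applied in order.  First, every sample whose instantaneous
velocity exceeds the spike cutoff (10 m/s; a value no rugby player reaches,
so such points are device artefacts) is removed together with its time
stamp, leaving a gap.  Second, a file losing more than 3% of its original
points is excluded from the analysis altogether.  Removed points are never
interpolated: a traversal across a gap would fabricate a velocity
transition that never happened.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trace import TraceParseError, VelocityTrace, read_trace

__all__ = ["CleaningReport", "CohortCleaningSummary", "clean_trace", "load_cohort"]

logger = logging.getLogger(__name__)

SPIKE_CUTOFF = 10.0          # m/s; strictly greater is removed, 10.0 itself kept
MAX_REMOVED_FRACTION = 0.03  # file excluded when removed fraction exceeds this


class EmptyTraceError(ValueError):
    """Cleaning was asked to operate on an empty trace."""


@dataclass(frozen=True)
class CleaningReport:
    """Outcome of cleaning one trace."""

    trace_id: str
    n_total: int
    n_removed: int
    retained: bool

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_total


@dataclass(frozen=True)
class CohortCleaningSummary:
    """Aggregate cleaning outcome over a set of files."""

    reports: list[CleaningReport]
    excluded: list[str]
    parse_failures: list[str]

    @property
    def n_files(self) -> int:
        return len(self.reports)

    @property
    def n_retained(self) -> int:
        return sum(r.retained for r in self.reports)


def clean_trace(
    trace: VelocityTrace,
    spike_cutoff: float = SPIKE_CUTOFF,
    max_removed_fraction: float = MAX_REMOVED_FRACTION,
) -> tuple[VelocityTrace, CleaningReport]:
    """Remove spike samples and decide file retention.

    Samples with velocity strictly greater than ``spike_cutoff`` are
    dropped with their time stamps (remaining stamps unchanged).  The
    removed fraction is taken over the original sample count; the trace is
    retained iff that fraction does not exceed ``max_removed_fraction``.
    """
    if len(trace) == 0:
        raise EmptyTraceError("cannot clean an empty trace")
    keep = trace.velocities <= spike_cutoff
    n_total = len(trace)
    n_removed = int(n_total - keep.sum())
    cleaned = trace if n_removed == 0 else trace.with_samples(
        trace.times[keep], trace.velocities[keep]
    )
    report = CleaningReport(
        trace_id=f"{trace.player_id}/{trace.match_id}",
        n_total=n_total,
        n_removed=n_removed,
        retained=(n_removed / n_total) <= max_removed_fraction,
    )
    return cleaned, report


def load_cohort(
    paths: list[str | Path],
    spike_cutoff: float = SPIKE_CUTOFF,
    max_removed_fraction: float = MAX_REMOVED_FRACTION,
    strict: bool = True,
) -> tuple[dict[str, list[VelocityTrace]], CohortCleaningSummary]:
    """Load, clean and filter a set of trace files, grouped by sex.

    Returns retained traces keyed by sex label, plus a summary listing
    excluded files and their reasons.  With ``strict`` (default) a
    malformed file raises; otherwise it is logged and skipped.
    """
    if not paths:
        raise ValueError("no trace files supplied")
    groups: dict[str, list[VelocityTrace]] = {}
    reports: list[CleaningReport] = []
    excluded: list[str] = []
    parse_failures: list[str] = []
    for p in paths:
        try:
            raw = read_trace(p)
        except TraceParseError as exc:
            if strict:
                raise
            logger.warning("skipping unparseable file: %s", exc)
            parse_failures.append(str(p))
            continue
        cleaned, rep = clean_trace(raw, spike_cutoff, max_removed_fraction)
        reports.append(rep)
        if rep.retained:
            groups.setdefault(cleaned.sex, []).append(cleaned)
            logger.info(
                "accepted %s: removed %d/%d points (%.2f%%)",
                p, rep.n_removed, rep.n_total, 100 * rep.removed_fraction,
            )
        else:
            excluded.append(str(p))
            logger.info(
                "excluded %s: removed fraction %.2f%% exceeds %.0f%%",
                p, 100 * rep.removed_fraction, 100 * max_removed_fraction,
            )
    return groups, CohortCleaningSummary(reports, excluded, parse_failures)
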