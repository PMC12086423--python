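"""CGM data cleaning and inclusion rules.

The cleaning pipeline is: discard the initial hours of each wear (sensor
warm-up / insertion artifact), flag implausible samples, drop the flagged
samples, then include the trace only if strictly more than a minimum number
of hours remain.  Wear time is counted as retained samples times the nominal
cadence, so recording gaps do not count as wear.

The implausibility detectors are heuristic stand-ins for visual curation:
flat-line runs (a sensor stuck on one value), physiologically impossible
rate-of-change jumps between adjacent samples, and extended pinning at the
sensor reporting rails (40/400 mg/dL).  All limits are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import GlucoseTrace, SENSOR_CEIL, SENSOR_FLOOR


@dataclass(frozen=True)
class ImplausibilityRules:
    """Detector settings for :func:`flag_implausible`."""

    flat_run_hours: float = 3.0      # identical-value run at least this long ...
    flat_min_count: int = 3          # ... and with at least this many samples
    jump_mg_dl_per_min: float = 15.0
    rail_minutes: float = 30.0
    rail_low: float = SENSOR_FLOOR
    rail_high: float = SENSOR_CEIL


@dataclass(frozen=True)
class QCConfig:
    trim_hours: float = 12.0
    min_remaining_hours: float = 96.0   # inclusion requires STRICTLY more
    max_flagged_fraction: float = 0.20  # bulk-implausibility exclusion
    interval_minutes: float = 5.0       # nominal cadence for wear-time accounting
    rules: ImplausibilityRules = field(default_factory=ImplausibilityRules)


@dataclass
class QCResult:
    """Outcome of quality control for one trace."""

    trace: GlucoseTrace                       # trimmed, flagged samples dropped
    hours_removed_initial: float
    implausible_spans: list[tuple[pd.Timestamp, pd.Timestamp]]
    flagged_fraction: float
    remaining_hours: float
    included: bool
    exclusion_reason: str                     # none | short_wear | implausible_bulk

    def to_row(self) -> dict:
        return {
            "participant_id": self.trace.participant_id,
            "session_id": self.trace.session_id,
            "lot_id": self.trace.lot_id,
            "hours_removed_initial": self.hours_removed_initial,
            "n_implausible_spans": len(self.implausible_spans),
            "flagged_fraction": self.flagged_fraction,
            "remaining_hours": self.remaining_hours,
            "days_of_data": self.remaining_hours / 24.0,
            "included": self.included,
            "exclusion_reason": self.exclusion_reason,
        }


def trim_initial(trace: GlucoseTrace, hours: float = 12.0) -> GlucoseTrace:
    """Drop all samples within ``hours`` of the first timestamp (half-open).

    A trace that records trim metadata at least as large as ``hours`` is
    returned unchanged, which makes the whole QC pipeline idempotent.
    """
    if trace.n_samples == 0:
        raise ValueError("cannot trim an empty trace")
    if trace.trimmed_hours >= hours:
        return trace
    cut = trace.times[0] + pd.Timedelta(hours=hours - trace.trimmed_hours)
    keep = trace.times >= cut
    return replace(
        trace,
        times=trace.times[keep],
        glucose=trace.glucose[keep],
        flags=trace.flags[keep],
        trimmed_hours=hours,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [i, j) of consecutive True values."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def flag_implausible(
    trace: GlucoseTrace, rules: ImplausibilityRules | None = None
) -> GlucoseTrace:
    """Return a copy with implausible samples flagged (existing flags kept)."""
    rules = rules or ImplausibilityRules()
    n = trace.n_samples
    flags = trace.flags.copy()
    if n == 0:
        return trace
    g = trace.glucose
    t_min = trace.times.asi8 / 60e9  # minutes

    # (a) flat-line: run of identical values, long enough in count and time
    same = np.concatenate(([False], np.diff(g) == 0))
    for i, j in _runs(same):
        lo = i - 1  # include the first sample of the identical run
        count = j - lo
        duration_h = (t_min[j - 1] - t_min[lo]) / 60.0
        if count >= rules.flat_min_count and duration_h >= rules.flat_run_hours:
            flags[lo:j] = True

    # (b) rate-of-change: flag both samples of an impossible step
    if n > 1:
        dt = np.diff(t_min)
        rate = np.abs(np.diff(g)) / np.where(dt > 0, dt, np.nan)
        bad = rate > rules.jump_mg_dl_per_min
        flags[:-1] |= bad
        flags[1:] |= bad

    # (c) pinned at the sensor rails for an extended period
    railed = (g <= rules.rail_low) | (g >= rules.rail_high)
    for i, j in _runs(railed):
        if t_min[j - 1] - t_min[i] >= rules.rail_minutes:
            flags[i:j] = True

    return replace(trace, flags=flags)


def qc_filter(trace: GlucoseTrace, config: QCConfig | None = None) -> QCResult:
    """Full QC pipeline: trim, flag, drop, apply inclusion rules."""
    config = config or QCConfig()
    removed = min(config.trim_hours, max(config.trim_hours - trace.trimmed_hours, 0.0))
    if trace.n_samples == 0:
        return QCResult(
            trace=trace, hours_removed_initial=0.0, implausible_spans=[],
            flagged_fraction=0.0, remaining_hours=0.0,
            included=False, exclusion_reason="short_wear",
        )
    trimmed = trim_initial(trace, config.trim_hours)
    flagged = flag_implausible(trimmed, config.rules)
    spans = [
        (flagged.times[i], flagged.times[j - 1])
        for i, j in _runs(flagged.flags)
    ]
    frac = float(flagged.flags.mean()) if flagged.n_samples else 0.0
    clean = flagged.retained()
    remaining_hours = clean.n_samples * config.interval_minutes / 60.0
    bulk = frac > config.max_flagged_fraction
    included = remaining_hours > config.min_remaining_hours and not bulk
    if included:
        reason = "none"
    elif bulk:
        reason = "implausible_bulk"
    else:
        reason = "short_wear"
    return QCResult(
        trace=clean,
        hours_removed_initial=removed,
        implausible_spans=spans,
        flagged_fraction=frac,
        remaining_hours=remaining_hours,
        included=included,
        exclusion_reason=reason,
    )


def qc_report(results: list[QCResult]) -> pd.DataFrame:
    """One row per trace with the QC outcome."""
    return pd.DataFrame([r.to_row() for r in results])
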