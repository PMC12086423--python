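"""Per-trace CGM summary parameters.

The parameter suite: mean, SD, CV (= 100·SD/mean), maximum, time above
140/160/180/200 mg/dL (TA, strict ``>``), time below 80/100 mg/dL (TB,
strict ``<``), the nocturnal mean over the [03:00, 06:00) clock-time window,
and wear time.  Time-in-range proportions are sample-count proportions — the
cadence is uniform after QC — and SD uses the population denominator ``n``
(with thousands of samples per wear the n/n−1 distinction is immaterial, but
the convention is fixed).

A useful consequence of these definitions: adding a constant offset ``c`` to
every reading shifts the mean, maximum and nocturnal mean by exactly ``c``,
leaves the SD unchanged, moves every TA up and every TB down — which is the
fingerprint of an additive sensor error, exploited by the correlation and
repeatability analyses downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .data import GlucoseTrace

TA_THRESHOLDS = (140.0, 160.0, 180.0, 200.0)
TB_THRESHOLDS = (80.0, 100.0)

#: the four discriminating parameters used for threshold and score analyses
DISCRIMINATING_METRICS = ("sd_glucose", "ta140", "ta160", "ta180")

NOCTURNAL_WINDOW = (3, 6)  # clock hours, half-open [03:00, 06:00)


@dataclass(frozen=True)
class CGMMetrics:
    participant_id: str
    session_id: str
    mean_glucose: float
    sd_glucose: float
    cv: float
    max_glucose: float
    ta140: float
    ta160: float
    ta180: float
    ta200: float
    tb80: float
    tb100: float
    nocturnal_mean: float
    wear_hours: float
    days_of_data: float

    def to_row(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRIC_FIELDS = [
    f.name for f in fields(CGMMetrics) if f.name not in ("participant_id", "session_id")
]


def _retained(trace: GlucoseTrace) -> tuple[pd.DatetimeIndex, np.ndarray]:
    keep = ~trace.flags
    return trace.times[keep], trace.glucose[keep]


def time_above(trace: GlucoseTrace, threshold: float) -> float:
    """Percent of retained samples with glucose strictly above ``threshold``."""
    _, g = _retained(trace)
    if g.size == 0:
        raise ValueError("empty trace")
    return 100.0 * float(np.count_nonzero(g > threshold)) / g.size


def time_below(trace: GlucoseTrace, threshold: float) -> float:
    """Percent of retained samples with glucose strictly below ``threshold``."""
    _, g = _retained(trace)
    if g.size == 0:
        raise ValueError("empty trace")
    return 100.0 * float(np.count_nonzero(g < threshold)) / g.size


def nocturnal_mean(trace: GlucoseTrace, pooled: bool = True) -> float:
    """Mean glucose over the [03:00, 06:00) clock window.

    ``pooled=True`` averages all nocturnal samples across nights; otherwise
    nightly means are computed first and then averaged (equal weight per
    night, robust to unequal nocturnal coverage).
    """
    t, g = _retained(trace)
    lo, hi = NOCTURNAL_WINDOW
    mask = (t.hour >= lo) & (t.hour < hi)
    if not mask.any():
        raise ValueError("no retained samples in the nocturnal window")
    if pooled:
        return float(g[mask].mean())
    per_night = pd.Series(g[mask]).groupby(t[mask].date).mean()
    return float(per_night.mean())


def compute_metrics(
    trace: GlucoseTrace,
    interval_minutes: float | None = None,
    pooled_nocturnal: bool = True,
) -> CGMMetrics:
    """Compute the full parameter suite for a QC-passed trace."""
    _, g = _retained(trace)
    if g.size == 0:
        raise ValueError("empty trace")
    if interval_minutes is None:
        interval_minutes = trace.interval_minutes
    mean = float(g.mean())
    sd = float(g.std(ddof=0))
    wear_hours = g.size * interval_minutes / 60.0
    ta = {thr: 100.0 * float(np.count_nonzero(g > thr)) / g.size for thr in TA_THRESHOLDS}
    tb = {thr: 100.0 * float(np.count_nonzero(g < thr)) / g.size for thr in TB_THRESHOLDS}
    return CGMMetrics(
        participant_id=trace.participant_id,
        session_id=trace.session_id,
        mean_glucose=mean,
        sd_glucose=sd,
        cv=100.0 * sd / mean,
        max_glucose=float(g.max()),
        ta140=ta[140.0],
        ta160=ta[160.0],
        ta180=ta[180.0],
        ta200=ta[200.0],
        tb80=tb[80.0],
        tb100=tb[100.0],
        nocturnal_mean=nocturnal_mean(trace, pooled=pooled_nocturnal),
        wear_hours=wear_hours,
        days_of_data=wear_hours / 24.0,
    )


def metrics_table(metrics: list[CGMMetrics]) -> pd.DataFrame:
    """One row per (participant, session)."""
    return pd.DataFrame([m.to_row() for m in metrics])
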